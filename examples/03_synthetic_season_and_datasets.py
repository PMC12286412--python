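"""Generate a synthetic season and assemble the five dataset variants.

Shows the data regime the evaluation operates in: a multi-week
microcycle calendar, rare match-day injuries, and the five feature
representations (raw baseline, three ACWR variants, footprint
variations) with pre-match undersampling.
"""

from fwf.datasets import VARIANTS, DatasetVariantSpec, build_feature_table, undersample_prematch
from fwf.features import WindowSet
from fwf.model import PlayerRoster
from fwf.simulate import generate_season, preset

cfg = preset("smoke_test", seed=3)
records, calendar, report, truth = generate_season(cfg)
roster = PlayerRoster(sorted(records["player_id"].unique().tolist()))

print(f"season: {len(roster)} players, {len(calendar)} events "
      f"({len(calendar.match_indices)} matches), {len(records)} workload records, "
      f"{len(report.entries)} injuries\n")

for variant in VARIANTS:
    taus = WindowSet((1, 2, 3, 4, 5)) if variant == "fwf" else None
    spec = DatasetVariantSpec(variant, taus=taus)
    table = build_feature_table(records, calendar, roster, report, spec)
    md1 = undersample_prematch(table, calendar, records)
    print(f"{variant:15s} assembled {len(table):4d} x {table.features.shape[1]:3d}"
          f"  ->  MD-1 only {len(md1):3d} rows, "
          f"{int(md1.labels.sum())} positives "
          f"(prevalence {md1.prevalence:.2f})")

# Each row of an undersampled table is one pre-match question: "given
# this player's workload features the day before the game, will they be
# injured in it?"  The fwf variant carries 2 columns (cumulative AW and
# differential ACW) per variable and window size; the baseline carries
# only the raw same-day values.
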