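"""Assembly of the five labelled dataset variants and the pre-match
(MD-1) undersampling.

The five variants share the same season but differ in feature
engineering:

    baseline_raw    the raw per-event variable values, participated
                    events only (no engineered columns) — the baseline
    acwr_uncoupled  per variable the (AW7, CW21, ratio) triplet
    acwr_coupled    per variable the (AW7, CW28, ratio) triplet
    acwr_ewma       per variable the (EWMA7, EWMA28, ratio) triplet
    fwf             per variable and window tau the (AW, ACW) pair from
                    the SigmaT-FWF and DeltaT-FWF matrices

Variants other than the baseline are computed on the zero-filled
calendar so every player shares the same event axis.  Feature columns
follow the convention ``{variable}__{operator}__{tau}`` so each table is
self-describing.

Undersampling keeps only MD-1 rows of players who then took part in the
following match, with match-day injury labels shifted back onto MD-1 —
the sample a practitioner actually scores the day before a game.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .features import (
    WindowSet,
    acwr_coupled,
    acwr_uncoupled,
    acute_workload,
    chronic_workload_21,
    chronic_workload_28,
    cumulative_matrix,
    ewma_series,
    temporal_matrix,
)
from .model import (
    SeasonCalendar,
    PlayerRoster,
    InjuryReport,
    build_fwf,
    build_injury_vector,
    participation_mask,
    records_to_frame,
    shift_match_labels_to_md1,
)

logger = logging.getLogger(__name__)

__all__ = ["VARIANTS", "DatasetVariantSpec", "FeatureTable", "build_feature_table",
           "undersample_prematch"]

VARIANTS = ("baseline_raw", "acwr_uncoupled", "acwr_coupled", "acwr_ewma", "fwf")


@dataclass(frozen=True)
class DatasetVariantSpec:
    """Which feature engineering to apply, and with what options."""

    variant: str
    taus: WindowSet | None = None          # fwf only
    missing_policy: str = "zero_fill"
    edge_policy: str = "zero_pad"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.variant == "fwf" and self.taus is None:
            raise ValueError("the fwf variant requires a window set (taus)")
        if self.variant != "fwf" and self.taus is not None:
            raise ValueError(f"taus is only meaningful for the fwf variant")

    def to_json_dict(self) -> dict:
        d = {"variant": self.variant,
             "taus": list(self.taus) if self.taus is not None else None,
             "missing_policy": self.missing_policy,
             "edge_policy": self.edge_policy}
        return d


@dataclass
class FeatureTable:
    """Labelled sample x feature table for one dataset variant.

    ``features`` is indexed by (player_id, event_index); ``labels`` is the
    aligned binary outcome.  ``prevalence`` is recorded at assembly time.
    """

    features: pd.DataFrame
    labels: pd.Series
    spec: DatasetVariantSpec

    def __post_init__(self) -> None:
        if not self.features.index.equals(self.labels.index):
            raise ValueError("features and labels must share one index")
        if self.features.isna().any().any():
            raise ValueError("feature table contains missing values")
        if not self.labels.isin((0, 1)).all():
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return len(self.features)

    @property
    def prevalence(self) -> float:
        return float(self.labels.mean()) if len(self.labels) else 0.0

    @property
    def X(self) -> np.ndarray:
        return self.features.to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.labels.to_numpy(dtype=int)

    def to_csv(self, path, sidecar_path=None) -> None:
        """Persist as CSV plus a JSON sidecar recording provenance."""
        out = self.features.copy()
        out["label"] = self.labels
        out.to_csv(path)
        if sidecar_path is not None:
            meta = {
                "spec": self.spec.to_json_dict(),
                "n_samples": len(self),
                "n_features": self.features.shape[1],
                "prevalence": self.prevalence,
                "columns": list(self.features.columns),
            }
            with open(sidecar_path, "w") as fh:
                json.dump(meta, fh, indent=2)


def _column(variable: str, operator: str, tau: int | None = None) -> str:
    return f"{variable}__{operator}__{tau}" if tau is not None else f"{variable}__{operator}"


def _nan_to_zero(x: float) -> float:
    # undefined ACWR (zero chronic load) becomes 0 in feature tables so
    # downstream models see a complete matrix; the raw operators keep NaN
    return 0.0 if np.isnan(x) else float(x)


def build_feature_table(
    records,
    calendar: SeasonCalendar,
    roster: PlayerRoster,
    report: InjuryReport,
    spec: DatasetVariantSpec,
    variables: list[str] | None = None,
) -> FeatureTable:
    """Assemble one labelled dataset variant for the whole roster.

    baseline_raw keeps only participated (player, event) rows with the
    raw variable values; all other variants are computed per player on
    the zero-filled calendar, so every player contributes one row per
    calendar event.
    """
    df = records_to_frame(records)
    if variables is None:
        variables = sorted(df["variable"].unique().tolist())
    if not variables:
        raise ValueError("variable set must be non-empty")

    rows: list[pd.DataFrame] = []
    for player in roster:
        injuries = build_injury_vector(report, calendar, player)
        if spec.variant == "baseline_raw":
            fwf = build_fwf(df, calendar, player, variables, missing_policy="omit_event")
            feats = fwf.to_frame().T  # events x variables
            labels = pd.Series(
                injuries.labels[fwf.event_indices], index=feats.index, name="label"
            )
        else:
            fwf = build_fwf(df, calendar, player, variables, missing_policy="zero_fill")
            feats = _engineer(fwf, spec)
            labels = pd.Series(injuries.labels, index=feats.index, name="label")
        feats.index = pd.MultiIndex.from_product(
            [[player], feats.index], names=["player_id", "event_index"]
        )
        labels.index = feats.index
        block = feats.copy()
        block["label"] = labels
        rows.append(block)

    table = pd.concat(rows)
    labels = table.pop("label").astype(int)
    return FeatureTable(features=table, labels=labels, spec=spec)


def _engineer(fwf, spec: DatasetVariantSpec) -> pd.DataFrame:
    """Per-player engineered features, one row per calendar event."""
    n_e = len(fwf.event_indices)
    cols: dict[str, np.ndarray] = {}
    if spec.variant == "fwf":
        cum = cumulative_matrix(fwf, spec.taus, spec.edge_policy)
        tem = temporal_matrix(fwf, spec.taus, spec.edge_policy)
        for vi, var in enumerate(fwf.variables):
            for ti, tau in enumerate(spec.taus):
                cols[_column(var, "aw", tau)] = cum.values[vi, :, ti]
                cols[_column(var, "acw", tau)] = tem.values[vi, :, ti]
    elif spec.variant in ("acwr_coupled", "acwr_uncoupled"):
        chronic_fn = chronic_workload_28 if spec.variant == "acwr_coupled" else chronic_workload_21
        chronic_name = "cw28" if spec.variant == "acwr_coupled" else "cw21"
        ratio_fn = acwr_coupled if spec.variant == "acwr_coupled" else acwr_uncoupled
        for var in fwf.variables:
            series = fwf.series(var)
            cols[_column(var, "aw7")] = np.array(
                [acute_workload(series, j, 7, spec.edge_policy) for j in range(n_e)]
            )
            cols[_column(var, chronic_name)] = np.array(
                [chronic_fn(series, j, spec.edge_policy) for j in range(n_e)]
            )
            cols[_column(var, "acwr")] = np.array(
                [_nan_to_zero(ratio_fn(series, j, spec.edge_policy)) for j in range(n_e)]
            )
    elif spec.variant == "acwr_ewma":
        for var in fwf.variables:
            series = fwf.series(var)
            num = ewma_series(series, 7)
            den = ewma_series(series, 28)
            ratio = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
            cols[_column(var, "ewma7")] = num
            cols[_column(var, "ewma28")] = den
            cols[_column(var, "acwr")] = ratio
    else:  # pragma: no cover - guarded by DatasetVariantSpec
        raise ValueError(spec.variant)
    return pd.DataFrame(cols, index=fwf.event_indices)


def undersample_prematch(
    table: FeatureTable,
    calendar: SeasonCalendar,
    records,
) -> FeatureTable:
    """Keep only MD-1 rows of players who took part in the following match.

    Labels of the retained rows are the match-day-shifted labels: an
    injury realized at the match is the positive outcome of its MD-1
    sample.  Match-day and mid-week rows are removed.
    """
    md1_to_match: dict[int, int] = {}
    for m in calendar.match_indices:
        md1 = calendar.md1_for_match(m)
        if md1 is not None:
            md1_to_match[md1] = m
    if not md1_to_match:
        logger.warning("calendar has no MD-1 events; undersampled table is empty")

    df = records_to_frame(records)
    players = table.features.index.get_level_values("player_id").unique()
    keep: list[tuple[str, int]] = []
    new_labels: list[int] = []
    index_set = set(table.features.index)
    for player in players:
        part = participation_mask(df, calendar, player)
        # shifted labels carry the match outcome back onto MD-1
        shifted = shift_match_labels_to_md1(
            _vector_from_table(table, calendar, player), calendar
        )
        for md1, match in md1_to_match.items():
            if not (part[md1] and part[match]):
                continue
            if (player, md1) not in index_set:
                continue
            keep.append((player, md1))
            new_labels.append(int(shifted.labels[md1]))

    idx = pd.MultiIndex.from_tuples(keep, names=["player_id", "event_index"])
    feats = table.features.loc[idx]
    labels = pd.Series(new_labels, index=idx, name="label")
    return FeatureTable(features=feats, labels=labels, spec=table.spec)


def _vector_from_table(table: FeatureTable, calendar: SeasonCalendar, player: str):
    """Reconstruct a full-calendar injury vector from table labels."""
    from .model import InjuryVector

    labels = np.zeros(len(calendar), dtype=int)
    sub = table.labels.xs(player, level="player_id")
    for j, v in sub.items():
        if v:
            labels[int(j)] = 1
    return InjuryVector(player=player, labels=labels)
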