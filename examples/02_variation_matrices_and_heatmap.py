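"""Cumulative and temporal variation matrices, rendered as heatmaps.

Generates a small synthetic season, assembles one player's footprint,
stacks the tau-acute-workload (cumulative) and delta-ACW (temporal)
operators over a window set, and renders the two-panel explainability
heatmap for the last match week.
"""

from fwf.features import WindowSet, cumulative_matrix, temporal_matrix
from fwf.model import build_fwf
from fwf.simulate import generate_season, preset
from fwf.viz import HeatmapSpec, render_fwf_heatmaps

records, calendar, report, truth = generate_season(preset("smoke_test", seed=7))
player = "p01"
fwf = build_fwf(records, calendar, player, missing_policy="zero_fill")
taus = WindowSet((2, 3, 5, 7, 11, 13))

cum = cumulative_matrix(fwf, taus)
tem = temporal_matrix(fwf, taus)
event = calendar.md1_for_match(calendar.match_indices[-1])  # last MD-1

print(f"footprint shape (variables x events): {fwf.values.shape}")
print(f"cumulative block shape: {cum.to_block().shape}  (variables x events*taus)")
print(f"\ncumulative cross-section at event {event} (rows=variables, cols=tau):")
print(cum.event_slice(event).round(1))
print(f"\ntemporal cross-section at event {event}:")
print(tem.event_slice(event).round(1))

spec = HeatmapSpec(player=player, event_index=event, taus=taus)
_fig, written = render_fwf_heatmaps(cum, tem, spec, "scratch/footprint_heatmap.png")
print(f"\nheatmap written to {written[0]}")
# The left (sequential) panel shows accumulated load per window size; the
# right (diverging) panel shows signed load changes — red cells flag
# spikes relative to tau events earlier, blue cells flag tapering.
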