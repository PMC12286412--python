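"""Explainability heatmaps of the footprint variation matrices.

For one player at one event, two panels are drawn: the cumulative
(SigmaT) panel on a sequential palette — acute workloads are
non-negative — and the temporal (DeltaT) panel on a diverging palette
centered at zero, since lagged differences are signed.  Variables run
along the x-axis, window sizes tau along the y-axis, so a column shows
how one variable's history accumulates (or swings) across time scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless rendering; callers save to files

import matplotlib.pyplot as plt
import numpy as np
import seaborn as sns

from .features import CumulativeMatrix, TemporalMatrix, WindowSet

__all__ = ["HeatmapSpec", "render_fwf_heatmaps"]


@dataclass(frozen=True)
class HeatmapSpec:
    """What to render: one (player, event) cross-section of both matrices."""

    player: str
    event_index: int
    taus: WindowSet = field(default_factory=WindowSet.primes_to_29)
    variables: tuple[str, ...] | None = None   # None = all
    annotations: tuple[str, ...] = ()
    normalize: str = "none"                    # none | per_variable | global
    cmap_cumulative: str = "YlOrRd"
    cmap_temporal: str = "RdBu_r"

    def __post_init__(self) -> None:
        if len(self.taus) == 0:
            raise ValueError("tau set must be non-empty")
        if self.normalize not in ("none", "per_variable", "global"):
            raise ValueError(f"unknown normalize mode {self.normalize!r}")


def _panel_data(matrix, spec: HeatmapSpec) -> np.ndarray:
    """tau x variable cross-section at the requested event (read-only)."""
    if matrix.player != spec.player:
        raise KeyError(
            f"matrix belongs to player {matrix.player!r}, spec asks for {spec.player!r}"
        )
    if spec.event_index not in matrix.event_indices:
        raise KeyError(f"event {spec.event_index} not in matrix")
    frame = matrix.event_slice(spec.event_index)  # variables x taus
    if spec.variables is not None:
        missing = set(spec.variables) - set(frame.index)
        if missing:
            raise KeyError(f"unknown variables: {sorted(missing)}")
        frame = frame.loc[list(spec.variables)]
    taus = [t for t in spec.taus if t in frame.columns]
    if not taus:
        raise KeyError("no requested tau present in the matrices")
    data = frame[taus].to_numpy(dtype=float).T.copy()  # taus x variables
    if spec.normalize == "per_variable":
        scale = np.abs(data).max(axis=0)
        scale[scale == 0] = 1.0
        data = data / scale
    elif spec.normalize == "global":
        scale = np.abs(data).max()
        data = data / (scale if scale > 0 else 1.0)
    return data, list(frame.index), taus


def render_fwf_heatmaps(
    cumulative: CumulativeMatrix,
    temporal: TemporalMatrix,
    spec: HeatmapSpec,
    out_path,
    formats: tuple[str, ...] = ("png",),
    dpi: int = 120,
):
    """Render the two-panel footprint heatmap and write image file(s).

    Returns (figure, written paths).  The figure is also returned so
    tests and notebooks can inspect the rendered arrays without touching
    the filesystem.
    """
    if list(cumulative.taus) != list(temporal.taus) or \
            cumulative.variables != temporal.variables:
        raise ValueError("cumulative and temporal matrices must share axes")

    cum_data, variables, taus = _panel_data(cumulative, spec)
    tem_data, _, _ = _panel_data(temporal, spec)

    fig, axes = plt.subplots(
        1, 2, figsize=(max(6, 1.0 * len(variables) + 3) * 2, max(3.5, 0.4 * len(taus) + 2))
    )
    sns.heatmap(
        cum_data, ax=axes[0], cmap=spec.cmap_cumulative,
        xticklabels=variables, yticklabels=taus,
        cbar_kws={"label": "acute workload"},
    )
    axes[0].set_title(
        f"Cumulative variations (sum over last tau events)\n"
        f"player {spec.player}, event {spec.event_index}"
    )
    lim = np.abs(tem_data).max()
    lim = lim if lim > 0 else 1.0
    sns.heatmap(
        tem_data, ax=axes[1], cmap=spec.cmap_temporal, vmin=-lim, vmax=lim,
        xticklabels=variables, yticklabels=taus,
        cbar_kws={"label": "workload change"},
    )
    axes[1].set_title(
        f"Temporal variations (change vs tau events back)\n"
        f"player {spec.player}, event {spec.event_index}"
    )
    for ax in axes:
        ax.set_xlabel("variable")
        ax.set_ylabel("window size tau (events)")
    for i, note in enumerate(spec.annotations):
        fig.text(0.01, 0.01 + 0.03 * i, note, fontsize=8)
    fig.tight_layout()

    out_path = Path(out_path)
    written = []
    for fmt in formats:
        target = out_path if out_path.suffix == f".{fmt}" else out_path.with_suffix(f".{fmt}")
        fig.savefig(target, dpi=dpi, format=fmt, metadata=_stable_metadata(fmt))
        written.append(target)
    return fig, written


def _stable_metadata(fmt: str) -> dict | None:
    # strip run-dependent metadata so identical inputs give identical bytes
    if fmt == "png":
        return {"Software": None}
    if fmt == "svg":
        return {"Date": None}
    return None
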