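"""Workload operators: generalized acute workload, chronic workloads, the
three classical ACWR variants, and the FWF cumulative / temporal variation
matrices.

All windows are *event-count* windows: "7" means the last 7 calendar
events (training sessions and matches), not 7 calendar days.  The acute
workload of variable v at event j over window tau is

    AW(j, tau) = sum_{z = j-tau+1}^{j} x_v(z)

so tau = 7 recovers the classical weekly acute load.  The chronic
workload CW28 is the average of the four consecutive weekly acute blocks
ending at j (equivalently sum of the last 28 values / 4); CW21 averages
the three weekly blocks *preceding* the acute week.  The three ACWR
variants are then

    coupled    AW(j,7) / CW28(j)        (acute week inside the chronic window)
    uncoupled  AW(j,7) / CW21(j)        (acute week excluded)
    EWMA       EWMA_7(x)[j] / EWMA_28(x)[j]

with EWMA_N the exponentially weighted moving average of the raw series
at smoothing weight lambda = 2 / (N + 1).

The differential operator is the first difference of the acute workload,

    ACW(j, tau) = AW(j, tau) - AW(j-1, tau) = x(j) - x(j - tau),

a telescoping identity that makes ACW a lagged-difference (spike)
detector.  Stacking AW and ACW over a window set T for every variable
and event yields the SigmaT-FWF (cumulative) and DeltaT-FWF (temporal)
matrices, the feature blocks of the footprint framework.

Season starts are handled by an edge policy: ``zero_pad`` (default)
treats pre-season history as zero load, matching the zero-fill
convention of the calendar-aligned datasets; ``strict`` raises when a
window would reach before event 0.  A ``history_complete`` flag on the
matrix types lets callers mask warm-up events where zero padding was
actually used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "UNDEFINED",
    "WindowSet",
    "AcwrTriplet",
    "CumulativeMatrix",
    "TemporalMatrix",
    "InsufficientHistoryError",
    "acute_workload",
    "chronic_workload_28",
    "chronic_workload_21",
    "acwr_coupled",
    "acwr_uncoupled",
    "ewma_series",
    "acwr_ewma",
    "delta_acw",
    "cumulative_matrix",
    "temporal_matrix",
]

#: Tagged value for an ACWR whose chronic denominator is zero (a legitimate
#: pre-season state) — never an exception, never silently 0.
UNDEFINED = float("nan")


def is_undefined(x: float) -> bool:
    return isinstance(x, float) and math.isnan(x)


class InsufficientHistoryError(ValueError):
    """Strict edge policy: the window reaches before the first event."""


@dataclass(frozen=True)
class WindowSet:
    """Ordered set T of window sizes tau >= 1."""

    taus: tuple[int, ...]

    def __init__(self, taus) -> None:
        taus = tuple(int(t) for t in taus)
        if not taus:
            raise ValueError("window set must be non-empty")
        if any(t < 1 for t in taus):
            raise ValueError("window sizes must be >= 1")
        if any(b <= a for a, b in zip(taus, taus[1:])):
            raise ValueError("window sizes must be strictly increasing")
        object.__setattr__(self, "taus", taus)

    def __iter__(self):
        return iter(self.taus)

    def __len__(self) -> int:
        return len(self.taus)

    @classmethod
    def classic(cls) -> "WindowSet":
        """T = {1, ..., 28}: every window up to the chronic month."""
        return cls(range(1, 29))

    @classmethod
    def primes_to_29(cls) -> "WindowSet":
        """The compact heatmap set T = {2,3,5,6,7,11,13,17,19,23,29}."""
        return cls((2, 3, 5, 6, 7, 11, 13, 17, 19, 23, 29))


@dataclass(frozen=True)
class AcwrTriplet:
    """(acute, chronic, ratio) for one variable at one event."""

    variable: str
    event_index: int
    acute: float
    chronic: float
    ratio: float  # NaN = undefined (zero chronic load)

    @property
    def defined(self) -> bool:
        return not math.isnan(self.ratio)


def _check_edge(j: int, tau: int, edge_policy: str) -> None:
    if edge_policy not in ("zero_pad", "strict"):
        raise ValueError(f"unknown edge_policy {edge_policy!r}")
    if edge_policy == "strict" and j - (tau - 1) < 0:
        raise InsufficientHistoryError(
            f"window tau={tau} at event {j} reaches before the season start"
        )


def _padded(series: np.ndarray, z: int) -> float:
    return float(series[z]) if z >= 0 else 0.0


def acute_workload(series, j: int, tau: int, edge_policy: str = "zero_pad") -> float:
    """tau-acute-workload: sum of the series over events j-tau+1 .. j.

    ``tau=7`` is the classical weekly acute load; ``tau=1`` is the raw
    event value.  Under ``zero_pad`` out-of-range terms contribute 0.
    """
    series = np.asarray(series, dtype=float)
    if tau < 1:
        raise ValueError("tau must be >= 1")
    if not 0 <= j < len(series):
        raise IndexError(f"event index {j} out of range for series of length {len(series)}")
    _check_edge(j, tau, edge_policy)
    lo = max(0, j - tau + 1)
    return float(series[lo : j + 1].sum())


def chronic_workload_28(series, j: int, edge_policy: str = "zero_pad") -> float:
    """Coupled chronic workload: mean of the four weekly acute blocks ending
    at j, i.e. (sum of the last 28 values) / 4."""
    _check_edge(j, 28, edge_policy)
    return acute_workload(series, j, 28, edge_policy="zero_pad") / 4.0


def chronic_workload_21(series, j: int, edge_policy: str = "zero_pad") -> float:
    """Uncoupled chronic workload: mean of the three weekly blocks that
    precede the acute week, (sum over events j-27 .. j-7) / 3."""
    _check_edge(j, 28, edge_policy)
    if j - 7 < 0:
        return 0.0
    return (
        acute_workload(series, j - 7, 21, edge_policy="zero_pad") / 3.0
    )


def acwr_coupled(series, j: int, edge_policy: str = "zero_pad") -> float:
    """Coupled ACWR = AW(j,7) / CW28(j); NaN when the chronic load is 0."""
    aw = acute_workload(series, j, 7, edge_policy)
    cw = chronic_workload_28(series, j, edge_policy)
    return aw / cw if cw > 0 else UNDEFINED


def acwr_uncoupled(series, j: int, edge_policy: str = "zero_pad") -> float:
    """Uncoupled ACWR = AW(j,7) / CW21(j); NaN when the chronic load is 0."""
    aw = acute_workload(series, j, 7, edge_policy)
    cw = chronic_workload_21(series, j, edge_policy)
    return aw / cw if cw > 0 else UNDEFINED


def ewma_series(series, n_span: int, init_policy: str = "first_value") -> np.ndarray:
    """Exponentially weighted moving average with smoothing weight
    lambda = 2 / (N + 1).

    Recursion: EWMA[j] = lambda * x[j] + (1 - lambda) * EWMA[j-1].
    ``first_value`` seeds EWMA[0] = x[0]; ``zero`` seeds EWMA[0] from a
    zero pre-season state (EWMA[0] = lambda * x[0]).
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("cannot smooth an empty series")
    if n_span < 1:
        raise ValueError("span must be >= 1")
    lam = 2.0 / (n_span + 1.0)
    out = np.empty_like(series)
    if init_policy == "first_value":
        out[0] = series[0]
    elif init_policy == "zero":
        out[0] = lam * series[0]
    else:
        raise ValueError(f"unknown init_policy {init_policy!r}")
    for j in range(1, len(series)):
        out[j] = lam * series[j] + (1.0 - lam) * out[j - 1]
    return out


def acwr_ewma(series, j: int, init_policy: str = "first_value") -> float:
    """EWMA ACWR: ratio of the 7-span to the 28-span EWMA of the raw
    series at event j; NaN when the denominator is 0."""
    series = np.asarray(series, dtype=float)
    num = ewma_series(series, 7, init_policy)[j]
    den = ewma_series(series, 28, init_policy)[j]
    return num / den if den > 0 else UNDEFINED


def delta_acw(series, j: int, tau: int, edge_policy: str = "zero_pad") -> float:
    """Differential acute workload ACW(j, tau) = AW(j,tau) - AW(j-1,tau).

    By telescoping this equals x(j) - x(j - tau) exactly (the earlier
    term is 0-padded before the season start), so ACW measures the load
    change against the same point tau events earlier — a spike detector.
    """
    series = np.asarray(series, dtype=float)
    if tau < 1:
        raise ValueError("tau must be >= 1")
    if edge_policy == "strict" and j - tau < 0:
        raise InsufficientHistoryError(
            f"delta window tau={tau} at event {j} reaches before the season start"
        )
    if not 0 <= j < len(series):
        raise IndexError(f"event index {j} out of range")
    return float(series[j]) - _padded(series, j - tau)


# ---------------------------------------------------------------------------
# FWF variation matrices
# ---------------------------------------------------------------------------


def _rolling_sums(values: np.ndarray, tau: int) -> np.ndarray:
    """Vectorized AW(., tau) for every row of a (#V, #E) matrix, zero-padded."""
    csum = np.cumsum(values, axis=1)
    out = csum.copy()
    if tau < values.shape[1]:
        out[:, tau:] = csum[:, tau:] - csum[:, :-tau]
    return out


@dataclass
class _VariationMatrix:
    """Common container for the SigmaT / DeltaT feature blocks.

    ``values`` has shape (#V, #E, #T); ``to_block`` flattens it to the
    printed #V x (#E * #T) layout, tau-major within each event, with
    explicit axis labels so the flattening order is unambiguous.
    """

    player: str
    variables: list[str]
    event_indices: list[int]
    taus: WindowSet
    values: np.ndarray
    history_complete: np.ndarray = field(default=None)  # (#E, #T) bool

    def __post_init__(self) -> None:
        expected = (len(self.variables), len(self.event_indices), len(self.taus))
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != {expected}")
        if self.history_complete is None:
            n_e, n_t = len(self.event_indices), len(self.taus)
            hc = np.empty((n_e, n_t), dtype=bool)
            for ti, tau in enumerate(self.taus):
                hc[:, ti] = np.array(self.event_indices) >= tau - 1
            self.history_complete = hc

    def cell(self, variable: str, event_index: int, tau: int) -> float:
        vi = self.variables.index(variable)
        ej = self.event_indices.index(event_index)
        ti = list(self.taus).index(tau)
        return float(self.values[vi, ej, ti])

    def to_block(self) -> pd.DataFrame:
        """#V x (#E * #T) block with a (event, tau) column MultiIndex."""
        n_v, n_e, n_t = self.values.shape
        cols = pd.MultiIndex.from_product(
            [self.event_indices, list(self.taus)], names=["event_index", "tau"]
        )
        return pd.DataFrame(
            self.values.reshape(n_v, n_e * n_t), index=self.variables, columns=cols
        )

    def to_tidy(self, value_name: str) -> pd.DataFrame:
        """Long form: player, variable, event_index, tau, <value_name>."""
        block = self.to_block().stack([0, 1], future_stack=True)
        df = block.rename(value_name).reset_index()
        df.columns = ["variable", "event_index", "tau", value_name]
        df.insert(0, "player", self.player)
        return df

    def event_slice(self, event_index: int) -> pd.DataFrame:
        """#V x #T cross-section at one event (heatmap panel data)."""
        ej = self.event_indices.index(event_index)
        return pd.DataFrame(
            self.values[:, ej, :], index=self.variables, columns=list(self.taus)
        )


class CumulativeMatrix(_VariationMatrix):
    """SigmaT-FWF: AW(v, e, tau) over the window set T."""


class TemporalMatrix(_VariationMatrix):
    """DeltaT-FWF: ACW(v, e, tau) over the window set T."""


def cumulative_matrix(fwf, taus: WindowSet, edge_policy: str = "zero_pad") -> CumulativeMatrix:
    """SigmaT-FWF feature block: every cell (v, e_j, tau) holds the
    tau-acute-workload of variable v at event e_j."""
    if fwf.missing_policy != "zero_fill":
        raise ValueError("variation matrices require a zero-filled footprint")
    taus = taus if isinstance(taus, WindowSet) else WindowSet(taus)
    n_e = len(fwf.event_indices)
    if edge_policy == "strict" and max(taus) > n_e:
        raise InsufficientHistoryError(
            f"max window {max(taus)} exceeds season length {n_e}"
        )
    vals = np.stack([_rolling_sums(fwf.values, tau) for tau in taus], axis=2)
    return CumulativeMatrix(
        player=fwf.player,
        variables=list(fwf.variables),
        event_indices=list(fwf.event_indices),
        taus=taus,
        values=vals,
    )


def temporal_matrix(fwf, taus: WindowSet, edge_policy: str = "zero_pad") -> TemporalMatrix:
    """DeltaT-FWF feature block: every cell (v, e_j, tau) holds
    ACW = x(e_j) - x(e_{j-tau}), zero-padded before the season start."""
    if fwf.missing_policy != "zero_fill":
        raise ValueError("variation matrices require a zero-filled footprint")
    taus = taus if isinstance(taus, WindowSet) else WindowSet(taus)
    n_v, n_e = fwf.values.shape
    vals = np.empty((n_v, n_e, len(taus)))
    for ti, tau in enumerate(taus):
        lagged = np.zeros_like(fwf.values)
        if tau < n_e:
            lagged[:, tau:] = fwf.values[:, :-tau]
        vals[:, :, ti] = fwf.values - lagged
    return TemporalMatrix(
        player=fwf.player,
        variables=list(fwf.variables),
        event_indices=list(fwf.event_indices),
        taus=taus,
        values=vals,
    )
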