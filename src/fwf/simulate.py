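"""Synthetic multi-player seasons with a planted, recoverable injury signal.

The generator emulates the statistical regime the footprint framework
assumes: a roster of players training in weekly microcycles
(MD-4 ... MD-1, match), tens of non-negative external-workload
variables, sparse participation, and rare match-day injuries whose
hazard is driven by recent workload *spikes*.

The planted mechanism is deliberately aligned with the differential
footprint operator: the per-match injury probability is

    p = logistic(beta0 + beta1 * z),
    z = standardized [ x_d(MD-1) - x_d(MD-1 - driver_tau) ]

for one driver variable d — i.e. exactly a Delta-ACW cell.  Players
carry heterogeneous baseline load multipliers, so the raw MD-1 value of
the driver is confounded by who the player is while the difference
cancels the baseline: feature sets built on lagged differences can
recover the signal where raw same-day values struggle.  beta0 is
calibrated by bisection so the mean simulated probability matches a
target match-day prevalence.

Workload values are lognormal around a per-variable, per-microcycle-day
mean (heavier MD-3 and match day, lighter MD-1), multiplied by an
occasional spike.  This is a statistical stand-in for real GPS load
data, not a calibrated emulator: it reproduces positivity, right skew,
microcycle shape, player heterogeneity and spike-driven hazard, nothing
biomechanical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import date as _date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import CalendarEvent, InjuryReport, PlayerRoster, SeasonCalendar

__all__ = ["SeasonConfig", "SyntheticTruth", "generate_season", "preset",
           "emulate_paper_scale", "write_season"]

# relative load by microcycle day: hardest sessions early-mid week and on
# match day, a light activation session on MD-1
MD_LOAD_SHAPE = {-4: 1.0, -3: 1.25, -2: 0.9, -1: 0.55, 0: 1.35}


@dataclass(frozen=True)
class SeasonConfig:
    """All knobs of the synthetic season."""

    n_players: int = 23
    n_weeks: int = 45
    microcycle: tuple[int, ...] = (-4, -3, -2, -1, 0)  # md offsets; 0 = match
    n_variables: int = 10
    baseline_mean: float = 100.0     # typical per-event load, arbitrary units
    baseline_sd: float = 0.25        # lognormal sigma of event-to-event noise
    variable_spread: float = 0.5     # lognormal sigma of per-variable means
    player_spread: float = 0.35      # lognormal sigma of per-player multipliers
    spike_probability: float = 0.10  # per (player, event, variable)
    spike_multiplier: float = 3.0
    beta1: float = 2.0               # hazard slope on the standardized driver diff
    driver_variable: str = "v1"
    driver_tau: int = 3
    participation_rate: float = 0.95
    target_prevalence: float = 0.025  # mean match-day injury probability
    training_hazard: float = 0.0      # per training event; 0 = match-only hazard
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.participation_rate <= 1.0:
            raise ValueError("participation_rate must be in (0, 1]")
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValueError("target_prevalence must be in (0, 1)")
        if not 0.0 <= self.spike_probability <= 1.0:
            raise ValueError("spike_probability must be in [0, 1]")
        if self.spike_multiplier <= 1.0:
            raise ValueError("spike_multiplier must be > 1")
        if 0 not in self.microcycle:
            raise ValueError("microcycle must contain the match day (offset 0)")
        if self.driver_variable not in self.variable_names():
            raise ValueError(
                f"driver variable {self.driver_variable!r} not among "
                f"{self.n_variables} generated variables"
            )
        if self.driver_tau < 1:
            raise ValueError("driver_tau must be >= 1")

    def variable_names(self) -> list[str]:
        return [f"v{i + 1}" for i in range(self.n_variables)]

    @classmethod
    def from_yaml(cls, path) -> "SeasonConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "microcycle" in raw:
            raw["microcycle"] = tuple(raw["microcycle"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["microcycle"] = list(d["microcycle"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class SyntheticTruth:
    """Ground truth of one generated season."""

    probabilities: dict          # (player, match_event) -> injury probability
    labels: dict                 # (player, match_event) -> 0/1
    spikes: list                 # (player, event, variable) with a spike
    beta0: float
    driver_variable: str
    driver_tau: int

    def to_json(self, path) -> None:
        out = {
            "beta0": self.beta0,
            "driver_variable": self.driver_variable,
            "driver_tau": self.driver_tau,
            "probabilities": [
                {"player_id": p, "event_index": j, "probability": v}
                for (p, j), v in sorted(self.probabilities.items())
            ],
            "labels": [
                {"player_id": p, "event_index": j, "label": v}
                for (p, j), v in sorted(self.labels.items())
            ],
            "spikes": [
                {"player_id": p, "event_index": j, "variable": v}
                for p, j, v in self.spikes
            ],
        }
        with open(path, "w") as fh:
            json.dump(out, fh, indent=2)


def _build_calendar(config: SeasonConfig, start: _date = _date(2024, 7, 1)) -> SeasonCalendar:
    events = []
    j = 0
    for week in range(config.n_weeks):
        for pos, md in enumerate(config.microcycle):
            events.append(
                CalendarEvent(
                    event_index=j,
                    date=start + timedelta(days=7 * week + pos),
                    event_type="match" if md == 0 else "training",
                    md_offset=md,
                )
            )
            j += 1
    return SeasonCalendar(events)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def _calibrate_beta0(z: np.ndarray, beta1: float, target: float) -> float:
    """Bisection on the intercept so that mean logistic(b0 + b1 z) = target."""
    lo, hi = -50.0, 50.0
    f = lambda b0: float(_sigmoid(b0 + beta1 * z).mean()) - target
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(
            f"target prevalence {target} unreachable with beta1={beta1} "
            f"(z range {z.min():.2f}..{z.max():.2f})"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_season(config: SeasonConfig):
    """Draw one season.

    Returns ``(records, calendar, report, truth)`` where ``records`` is
    the long-format workload DataFrame of :mod:`fwf.model`, ``report``
    the realized injuries, and ``truth`` the generating probabilities.
    Identical config (including seed) gives identical output.
    """
    rng = np.random.default_rng(config.seed)
    calendar = _build_calendar(config)
    players = [f"p{k + 1:02d}" for k in range(config.n_players)]
    variables = config.variable_names()
    n_e, n_p, n_v = len(calendar), len(players), len(variables)

    var_means = config.baseline_mean * np.exp(
        rng.normal(0.0, config.variable_spread, size=n_v)
    )
    player_mult = np.exp(rng.normal(0.0, config.player_spread, size=n_p))
    md_shape = np.array([MD_LOAD_SHAPE.get(e.md_offset, 1.0) for e in calendar])

    participates = rng.random((n_p, n_e)) < config.participation_rate
    noise = np.exp(rng.normal(0.0, config.baseline_sd, size=(n_p, n_e, n_v)))
    spike = rng.random((n_p, n_e, n_v)) < config.spike_probability
    values = (
        player_mult[:, None, None]
        * md_shape[None, :, None]
        * var_means[None, None, :]
        * noise
        * np.where(spike, config.spike_multiplier, 1.0)
    )
    values[~participates] = 0.0

    # hazard driver: Delta-ACW of the driver variable at MD-1, i.e. the
    # lagged difference x_d(MD-1) - x_d(MD-1 - driver_tau) on the
    # zero-filled event axis
    d_idx = variables.index(config.driver_variable)
    driver = values[:, :, d_idx]
    pairs: list[tuple[int, int, int]] = []  # (player_i, match_event, md1_event)
    for m in calendar.match_indices:
        md1 = calendar.md1_for_match(m)
        if md1 is None:
            continue
        for pi in range(n_p):
            if participates[pi, m]:
                pairs.append((pi, m, md1))
    if not pairs:
        raise ValueError("season has no (player, match) pairs with participation")
    diffs = np.array(
        [
            driver[pi, md1] - (driver[pi, md1 - config.driver_tau]
                               if md1 - config.driver_tau >= 0 else 0.0)
            for pi, _m, md1 in pairs
        ]
    )
    sd = diffs.std()
    z = (diffs - diffs.mean()) / (sd if sd > 0 else 1.0)
    beta0 = _calibrate_beta0(z, config.beta1, config.target_prevalence)
    probs = _sigmoid(beta0 + config.beta1 * z)
    draws = rng.random(len(pairs)) < probs

    probabilities, labels, entries = {}, {}, []
    for (pi, m, _md1), p, hit in zip(pairs, probs, draws):
        probabilities[(players[pi], m)] = float(p)
        labels[(players[pi], m)] = int(hit)
        if hit:
            entries.append((players[pi], m, "muscle"))

    if config.training_hazard > 0:
        for pi in range(n_p):
            for e in calendar:
                if e.event_type == "training" and participates[pi, e.event_index]:
                    if rng.random() < config.training_hazard:
                        entries.append((players[pi], e.event_index, "muscle"))

    # long-format records for participated events only
    p_idx, e_idx, v_idx = np.nonzero(values > 0)
    records = pd.DataFrame(
        {
            "player_id": np.array(players)[p_idx],
            "event_index": e_idx,
            "variable": np.array(variables)[v_idx],
            "value": values[p_idx, e_idx, v_idx],
        }
    ).sort_values(["player_id", "event_index", "variable"], kind="stable").reset_index(drop=True)

    spikes = [
        (players[pi], int(ej), variables[vi])
        for pi, ej, vi in zip(*np.nonzero(spike & participates[:, :, None]))
    ]
    truth = SyntheticTruth(
        probabilities=probabilities,
        labels=labels,
        spikes=spikes,
        beta0=beta0,
        driver_variable=config.driver_variable,
        driver_tau=config.driver_tau,
    )
    return records, calendar, InjuryReport(entries), truth


PRESETS = {
    # full-season regime: ~23 players x 45 weeks, 73 load variables,
    # sparse participation, ~2.5% match-day prevalence -> ~20 injuries
    "paper_scale": dict(
        n_players=23, n_weeks=45, n_variables=73,
        participation_rate=0.80, target_prevalence=0.025,
        spike_probability=0.10, spike_multiplier=3.0, beta1=2.0,
    ),
    # small fast regime for tests and examples; prevalence raised so the
    # ~48-row undersampled table still carries enough positives for
    # stratified 2-fold cross-validation
    "smoke_test": dict(
        n_players=6, n_weeks=8, n_variables=5,
        participation_rate=0.90, target_prevalence=0.25,
        spike_probability=0.15, spike_multiplier=3.0, beta1=2.5,
    ),
}


def preset(name: str, seed: int = 0, **overrides) -> SeasonConfig:
    """Named season configuration: ``paper_scale`` or ``smoke_test``."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return SeasonConfig(seed=seed, **kwargs)


# alias kept for discoverability next to the season-scale vocabulary
emulate_paper_scale = preset


def write_season(records, calendar: SeasonCalendar, report: InjuryReport,
                 truth: SyntheticTruth | None, out_dir) -> dict[str, Path]:
    """Write a generated season as the package's CSV interchange formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cal = pd.DataFrame(
        {
            "event_index": [e.event_index for e in calendar],
            "date": [e.date.isoformat() if e.date else "" for e in calendar],
            "event_type": [e.event_type for e in calendar],
            "md_offset": [e.md_offset for e in calendar],
        }
    )
    merged = records.merge(cal, on="event_index", how="left")
    cols = ["player_id", "event_index", "date", "event_type", "md_offset",
            "variable", "value"]
    paths = {"workload": out / "workload.csv", "injuries": out / "injuries.csv"}
    merged[cols].to_csv(paths["workload"], index=False)
    pd.DataFrame(report.entries,
                 columns=["player_id", "event_index", "injury_class"]
                 ).to_csv(paths["injuries"], index=False)
    if truth is not None:
        paths["truth"] = out / "truth.json"
        truth.to_json(paths["truth"])
    return paths
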