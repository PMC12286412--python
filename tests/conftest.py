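"""Shared fixtures: hand-built toy seasons and cached simulation studies."""

import numpy as np
import pandas as pd
import pytest

from fwf.model import (
    CalendarEvent,
    InjuryReport,
    PlayerRoster,
    SeasonCalendar,
)

# Weekly load pattern whose printed form is [1.5, 0.33, ...]: the light
# values are exactly one third, so every week sums to exactly 7 units.
THIRD = 1.0 / 3.0
WEEK_ALTERNATING = [1.5, THIRD, 1.5, THIRD, 1.5, THIRD, 1.5]
WEEK_BACKLOADED = [0, 0, 0, 0, 0, 0, 7]
WEEK_FLAT = [1, 1, 1, 1, 1, 1, 1]


@pytest.fixture
def microcycle_calendar():
    """4 microcycles of 5 events (MD-4..MD-1, match): 20 events."""
    events = []
    j = 0
    for _week in range(4):
        for md in (-4, -3, -2, -1, 0):
            events.append(
                CalendarEvent(
                    event_index=j,
                    date=None,
                    event_type="match" if md == 0 else "training",
                    md_offset=md,
                )
            )
            j += 1
    return SeasonCalendar(events)


@pytest.fixture
def toy_records(microcycle_calendar):
    """Two players, two variables, full participation except p2 skips
    event 7 entirely and the whole of match 2 (event 9)."""
    rows = []
    for player in ("p1", "p2"):
        for e in microcycle_calendar:
            j = e.event_index
            if player == "p2" and j in (7, 9):
                continue
            for vi, var in enumerate(("distance", "sprints")):
                rows.append((player, j, var, 10.0 * (vi + 1) + j))
    return pd.DataFrame(rows, columns=["player_id", "event_index", "variable", "value"])


@pytest.fixture
def toy_roster():
    return PlayerRoster(["p1", "p2"])


@pytest.fixture
def toy_report():
    # p1 injured at match of microcycle 3 (event 14); p2 at match 1 (event 4)
    return InjuryReport([("p1", 14, "muscle"), ("p2", 4, "muscle")])


@pytest.fixture(scope="session")
def smoke_season():
    """One cached smoke-scale synthetic season."""
    from fwf.simulate import generate_season, preset

    cfg = preset("smoke_test", seed=1)
    records, calendar, report, truth = generate_season(cfg)
    roster = PlayerRoster(sorted(records["player_id"].unique().tolist()))
    return records, calendar, roster, report, truth


@pytest.fixture(scope="session")
def comparison_study():
    """The 10-seed footprint-vs-baseline study (cached: it is the most
    expensive computation in the suite)."""
    from fwf.experiment import variant_comparison

    return variant_comparison(n_seeds=10, base_seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
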