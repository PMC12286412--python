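"""Workload operators: worked examples, oracles and algebraic identities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fwf.features import (
    InsufficientHistoryError,
    WindowSet,
    acute_workload,
    acwr_coupled,
    acwr_ewma,
    acwr_uncoupled,
    chronic_workload_21,
    chronic_workload_28,
    cumulative_matrix,
    delta_acw,
    ewma_series,
    temporal_matrix,
)
from fwf.model import FWFMatrix

from conftest import THIRD, WEEK_ALTERNATING, WEEK_BACKLOADED, WEEK_FLAT

F1_SEASON = WEEK_ALTERNATING * 3 + WEEK_BACKLOADED
F2_SEASON = WEEK_ALTERNATING * 3 + WEEK_FLAT
F3_SEASON = WEEK_ALTERNATING * 4


# -- independent oracles -----------------------------------------------------

def brute_aw(series, j, tau):
    return sum(series[z] for z in range(j - tau + 1, j + 1) if z >= 0)


def brute_ewma(series, n_span, j):
    lam = 2.0 / (n_span + 1.0)
    total = 0.0
    for k in range(j):
        total += lam * (1 - lam) ** k * series[j - k]
    return total + (1 - lam) ** j * series[0]


nonneg_series = st.lists(
    st.floats(min_value=0, max_value=100, allow_nan=False), min_size=8, max_size=20
)


class TestAcuteWorkload:
    def test_weekly_example(self):
        # alternating 1.5 / one-third loads over seven events sum to 7
        assert acute_workload(WEEK_ALTERNATING, 6, 7) == pytest.approx(7.0)

    def test_tau_one_is_the_raw_value(self, rng):
        s = rng.random(10)
        for j in range(10):
            assert acute_workload(s, j, 1) == pytest.approx(s[j])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(nonneg_series)
    def test_matches_brute_force_everywhere(self, s):
        for j in range(len(s)):
            for tau in range(1, len(s) + 2):
                assert acute_workload(s, j, tau) == pytest.approx(brute_aw(s, j, tau))

    def test_strict_policy_raises_without_history(self):
        with pytest.raises(InsufficientHistoryError):
            acute_workload([1, 2, 3], 1, 7, edge_policy="strict")

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(nonneg_series)
    def test_recurrence_and_monotonicity(self, s):
        for j in range(len(s)):
            prev = acute_workload(s, j, 1)
            for tau in range(2, len(s) + 1):
                cur = acute_workload(s, j, tau)
                extra = s[j - tau + 1] if j - tau + 1 >= 0 else 0.0
                assert cur == pytest.approx(prev + extra)
                assert cur >= prev - 1e-12  # non-negative series
                prev = cur


class TestChronicAndAcwr:
    @pytest.mark.parametrize("season", [F1_SEASON, F2_SEASON, F3_SEASON])
    def test_printed_four_week_seasons(self, season):
        # each printed weekly block sums to exactly 7 units
        assert chronic_workload_28(season, 27) == pytest.approx(7.0)
        assert acwr_coupled(season, 27) == pytest.approx(1.0)

    def test_uncoupled_on_printed_season(self):
        # CW21 = mean of the three weekly sums preceding the acute week
        assert chronic_workload_21(F1_SEASON, 27) == pytest.approx(7.0)
        assert acwr_uncoupled(F1_SEASON, 27) == pytest.approx(1.0)

    def test_constant_series_full_history(self):
        s = [1.0] * 28
        assert chronic_workload_28(s, 27) == pytest.approx(7.0)
        assert chronic_workload_21(s, 27) == pytest.approx(7.0)
        assert acwr_coupled(s, 27) == pytest.approx(1.0)
        assert acwr_uncoupled(s, 27) == pytest.approx(1.0)

    def test_zero_series_gives_undefined_ratio(self):
        s = [0.0] * 30
        assert math.isnan(acwr_coupled(s, 29))
        assert math.isnan(acwr_uncoupled(s, 29))
        assert math.isnan(acwr_ewma(s, 29))

    def test_chronic_oracles_on_random_series(self, rng):
        for _ in range(50):
            s = rng.random(40) * 10
            j = int(rng.integers(0, 40))
            blocks = [brute_aw(s, j - 7 * w, 7) for w in range(4)]
            assert chronic_workload_28(s, j) == pytest.approx(sum(blocks) / 4)
            assert chronic_workload_21(s, j) == pytest.approx(sum(blocks[1:]) / 3)


class TestEwma:
    def test_constant_series_is_fixed_point(self):
        out = ewma_series([3.5] * 10, 7)
        assert np.allclose(out, 3.5)

    def test_hand_recursion_half_weight(self):
        out = ewma_series([1, 0, 0, 0], 3)  # lambda = 0.5
        assert np.allclose(out, [1, 0.5, 0.25, 0.125])

    def test_closed_form_oracle(self, rng):
        for _ in range(20):
            s = rng.random(30)
            for n_span in (3, 7, 28):
                out = ewma_series(s, n_span)
                for j in (0, 5, 29):
                    assert abs(out[j] - brute_ewma(s, n_span, j)) < 1e-10

    def test_constant_series_acwr_is_one(self):
        assert acwr_ewma([2.0] * 20, 19) == pytest.approx(1.0)

    def test_empty_series_raises(self):
        with pytest.raises(ValueError):
            ewma_series([], 7)


class TestDeltaAcw:
    def test_constant_series_is_zero_with_full_history(self):
        # before event tau the lagged term is zero-padded, so the
        # telescoping identity starts once the window is fully inside
        s = [4.0] * 15
        for tau in (1, 3, 7):
            for j in range(tau, 15):
                assert delta_acw(s, j, tau) == pytest.approx(0.0)

    def test_printed_backloaded_season(self):
        # last event of the flat fourth week vs one week earlier
        assert delta_acw(F2_SEASON, 27, 7) == pytest.approx(1.0 - 1.5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(nonneg_series)
    def test_equals_aw_difference_exactly(self, s):
        for j in range(1, len(s)):
            for tau in range(1, len(s)):
                aw_diff = brute_aw(s, j, tau) - brute_aw(s, j - 1, tau)
                lagged = s[j] - (s[j - tau] if j - tau >= 0 else 0.0)
                assert delta_acw(s, j, tau) == pytest.approx(lagged)
                assert delta_acw(s, j, tau) == pytest.approx(aw_diff)

    def test_strict_policy(self):
        with pytest.raises(InsufficientHistoryError):
            delta_acw([1, 2, 3], 1, 5, edge_policy="strict")


class TestWindowSet:
    def test_rejects_non_increasing(self):
        with pytest.raises(ValueError):
            WindowSet((3, 2))

    def test_rejects_empty_and_nonpositive(self):
        with pytest.raises(ValueError):
            WindowSet(())
        with pytest.raises(ValueError):
            WindowSet((0, 1))

    def test_named_sets(self):
        assert list(WindowSet.classic()) == list(range(1, 29))
        assert 29 in WindowSet.primes_to_29().taus


def _fwf_from_series(series_by_var):
    variables = list(series_by_var)
    values = np.array([series_by_var[v] for v in variables], dtype=float)
    return FWFMatrix(
        player="p1",
        variables=variables,
        event_indices=list(range(values.shape[1])),
        values=values,
    )


class TestVariationMatrices:
    def test_weekly_example_cell(self):
        fwf = _fwf_from_series({"v1": WEEK_ALTERNATING})
        cum = cumulative_matrix(fwf, WindowSet((7,)))
        assert cum.cell("v1", 6, 7) == pytest.approx(7.0)

    def test_tau_one_recovers_the_footprint(self, rng):
        fwf = _fwf_from_series({"a": rng.random(12), "b": rng.random(12)})
        cum = cumulative_matrix(fwf, WindowSet((1,)))
        assert np.allclose(cum.values[:, :, 0], fwf.values)

    def test_cellwise_oracle(self, rng):
        fwf = _fwf_from_series({"a": rng.random(15), "b": rng.random(15)})
        taus = WindowSet((1, 3, 5, 11))
        cum = cumulative_matrix(fwf, taus)
        tem = temporal_matrix(fwf, taus)
        for vi, var in enumerate(fwf.variables):
            s = fwf.values[vi]
            for j in range(15):
                for ti, tau in enumerate(taus):
                    assert cum.values[vi, j, ti] == pytest.approx(brute_aw(s, j, tau))
                    lag = s[j] - (s[j - tau] if j - tau >= 0 else 0.0)
                    assert tem.values[vi, j, ti] == pytest.approx(lag)

    def test_temporal_is_first_difference_of_cumulative(self, rng):
        fwf = _fwf_from_series({"a": rng.random(20)})
        taus = WindowSet((2, 7))
        cum = cumulative_matrix(fwf, taus)
        tem = temporal_matrix(fwf, taus)
        assert np.allclose(tem.values[:, 1:, :], np.diff(cum.values, axis=1))

    def test_constant_footprint_gives_zero_temporal(self):
        fwf = _fwf_from_series({"a": [2.0] * 10})
        tem = temporal_matrix(fwf, WindowSet((1, 2, 3)))
        # zero everywhere the window has complete history (warm-up events
        # compare against the zero-padded pre-season instead)
        for ti, tau in enumerate((1, 2, 3)):
            assert np.allclose(tem.values[:, tau:, ti], 0.0)
            assert np.allclose(tem.values[:, :tau, ti], 2.0)
        assert tem.history_complete[0, 2] == False  # noqa: E712
        assert tem.history_complete[9, 2] == True  # noqa: E712

    def test_block_layout_is_tau_major_within_event(self, rng):
        fwf = _fwf_from_series({"a": rng.random(4)})
        taus = WindowSet((1, 2))
        block = cumulative_matrix(fwf, taus).to_block()
        assert list(block.columns.names) == ["event_index", "tau"]
        assert block.columns[0] == (0, 1) and block.columns[1] == (0, 2)
        assert block.shape == (1, 8)

    def test_requires_zero_filled_footprint(self, rng):
        fwf = _fwf_from_series({"a": rng.random(4)})
        fwf.missing_policy = "omit_event"
        with pytest.raises(ValueError):
            cumulative_matrix(fwf, WindowSet((1,)))
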