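"""Trajectory statistics: oracles and invariants."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from chaperostart.analysis import (
    align_last_budding,
    detect_sep,
    interdivision_times,
    lifespan_summary,
    logistic_event_model,
    mann_whitney_u,
    survival_curve,
    survival_at,
)
from chaperostart.engine import LineageTrace


def make_trace(bud_times, observables=None, dt=10.0, extra_time=0.0):
    bud_times = np.asarray(bud_times, dtype=float)
    t_end = bud_times[-1] + extra_time
    grid = np.arange(0.0, t_end + dt / 2, dt)
    df = pd.DataFrame({"time_min": grid, "phase": "G1",
                       "generation": 0, "volume_fL": 30.0})
    for name, fn in (observables or {}).items():
        df[name] = fn(grid)
    events = [(float(t), "budding") for t in bud_times]
    events.append((t_end, "arrest"))
    return LineageTrace(samples=df, events=events,
                        lifespan=len(bud_times), censored=False)


class TestInterdivisionTimes:
    def test_durations_are_differences_of_budding_times(self):
        tr = make_trace([0.0, 100.0, 200.0])
        out = interdivision_times(tr)
        np.testing.assert_array_equal(out["duration_min"], [100.0, 100.0])
        np.testing.assert_array_equal(out["generation"], [1, 2])
        # exact agreement with the raw event log
        np.testing.assert_array_equal(
            out["duration_min"], np.diff(tr.budding_times))

    def test_single_budding_gives_empty_series(self):
        assert len(interdivision_times(make_trace([0.0]))) == 0


class TestAlignLastBudding:
    def test_identical_constant_traces_zero_width_band(self):
        traces = [make_trace([0, 90, 180], {"f": lambda t: 7.0 + 0 * t})
                  for _ in range(5)]
        ens = align_last_budding(traces, "f")
        ok = ens.n >= 2
        np.testing.assert_allclose(ens.mean[ok], 7.0)
        np.testing.assert_allclose(ens.ci_high[ok] - ens.ci_low[ok], 0.0,
                                   atol=1e-12)

    def test_single_trace_mean_equals_trace(self):
        tr = make_trace([0, 90, 180], {"f": lambda t: t * 2.0})
        ens = align_last_budding([tr], "f")
        inside = ens.n == 1
        expected = 2.0 * (ens.rel_time[inside] + 180.0)
        np.testing.assert_allclose(ens.mean[inside], expected)

    def test_planted_ramp_slopes_average(self):
        slopes = [0.5, 1.0, 1.5, 2.0]
        traces = [make_trace([0, 100, 200],
                             {"f": lambda t, a=a: a * t})
                  for a in slopes]
        ens = align_last_budding(traces, "f")
        full = ens.n == len(slopes)
        fit = np.polyfit(ens.rel_time[full], ens.mean[full], 1)
        assert fit[0] == pytest.approx(np.mean(slopes), abs=1e-9)

    def test_missing_observable_is_named(self):
        with pytest.raises(KeyError, match="nope"):
            align_last_budding([make_trace([0, 90])], "nope")

    def test_order_invariance(self):
        traces = [make_trace([0, 80 + 10 * i, 200],
                             {"f": lambda t, i=i: t + i})
                  for i in range(4)]
        a = align_last_budding(traces, "f")
        b = align_last_budding(traces[::-1], "f")
        np.testing.assert_allclose(a.mean, b.mean, equal_nan=True)


class TestSurvivalCurve:
    def test_uncensored_step_values(self):
        curve = survival_curve(np.array([1, 2, 3]))
        assert survival_at(curve, 0) == pytest.approx(1.0)
        assert survival_at(curve, 1) == pytest.approx(2 / 3)
        assert survival_at(curve, 2) == pytest.approx(1 / 3)
        assert survival_at(curve, 3) == pytest.approx(0.0)

    def test_all_equal_single_step(self):
        curve = survival_curve(np.array([5, 5, 5, 5]))
        s = curve["survival"].to_numpy()
        assert (s[:-1] == 1.0).all() and s[-1] == 0.0

    def test_monotone_bounded_and_integral_equals_mean(self):
        rng = np.random.default_rng(1)
        lifespans = rng.integers(1, 40, size=60)
        curve = survival_curve(lifespans)
        s = curve["survival"].to_numpy()
        assert np.all(np.diff(s) <= 1e-12)
        assert np.all((s >= 0) & (s <= 1))
        # sum_g S(g) over g >= 0 equals the mean for uncensored cohorts
        assert s.sum() == pytest.approx(lifespans.mean())

    def test_censoring_floor(self):
        curve = survival_curve(np.array([2, 3, 4, 4]),
                               censored=np.array([0, 0, 1, 1], bool))
        assert survival_at(curve, 4) > 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            survival_curve(np.array([]))


class TestDetectSep:
    def test_constant_series_no_sep(self):
        assert detect_sep(np.full(30, 100.0)) is None

    def test_planted_changepoint_found(self):
        series = np.concatenate([np.full(20, 100.0), np.full(3, 250.0)])
        assert detect_sep(series) == 21

    def test_transient_excursion_not_sustained(self):
        series = np.full(30, 100.0)
        series[12] = 400.0  # recovers afterwards: not a SEP
        assert detect_sep(series) is None

    def test_short_series_warns_and_returns_none(self):
        with pytest.warns(UserWarning):
            assert detect_sep(np.array([90.0, 95.0, 92.0, 91.0])) is None

    def test_no_false_positives_on_noisy_constant_series(self):
        rng = np.random.default_rng(42)
        hits = 0
        for _ in range(1000):
            series = rng.normal(100.0, 5.0, size=25)
            if detect_sep(series) is not None:
                hits += 1
        assert hits == 0


def _loglik(x, y, b0, b1):
    z = b0 + b1 * x
    return np.sum(y * z - np.log1p(np.exp(z)))


class TestLogisticEventModel:
    def test_two_by_two_closed_form_odds_ratio(self):
        # a=30 (x=1,y=1), b=10 (x=1,y=0), c=15, d=45 -> OR = (30*45)/(10*15)
        x = np.r_[np.ones(40), np.zeros(60)]
        y = np.r_[np.ones(30), np.zeros(10), np.ones(15), np.zeros(45)]
        fit = logistic_event_model(x, y)
        assert fit.odds_ratio == pytest.approx((30 * 45) / (10 * 15),
                                               rel=1e-5)
        assert fit.or_ci[0] < fit.odds_ratio < fit.or_ci[1]

    def test_recovers_generating_slope(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0.0, 1.0, size=1000)
        p = 1 / (1 + np.exp(-(-2.0 + 1.5 * x)))
        y = (rng.random(1000) < p).astype(float)
        fit = logistic_event_model(x, y)
        se = math.log(fit.or_ci[1] / fit.odds_ratio) / 1.959964
        assert abs(fit.slope - 1.5) < 1.959964 * se + 1e-12

    def test_perfect_separation_flagged(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = x.copy()
        fit = logistic_event_model(x, y)
        assert fit.separation
        assert fit.or_ci[1] == math.inf

    def test_matches_independent_profile_likelihood(self):
        # golden-section maximization over the slope at the MLE intercept
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = 120
            x = rng.normal(size=n)
            p = 1 / (1 + np.exp(-(0.3 - 0.8 * x)))
            y = (rng.random(n) < p).astype(float)
            fit = logistic_event_model(x, y)
            gr = (math.sqrt(5) - 1) / 2
            a, b = fit.slope - 0.5, fit.slope + 0.5
            for _ in range(80):
                c, d = b - gr * (b - a), a + gr * (b - a)
                if _loglik(x, y, fit.intercept, c) < \
                        _loglik(x, y, fit.intercept, d):
                    a = c
                else:
                    b = d
            assert abs((a + b) / 2 - fit.slope) < 1e-4

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            logistic_event_model(np.arange(5.0), np.ones(5))


def _exact_mw_p(a, b):
    """Full permutation enumeration of the two-sided Mann-Whitney p-value."""
    pooled = np.concatenate([a, b])
    na = len(a)
    def u_stat(idx):
        aa = pooled[list(idx)]
        bb = np.delete(pooled, list(idx))
        u = sum((x > y) + 0.5 * (x == y) for x in aa for y in bb)
        return u
    u_obs = u_stat(range(na))
    mu = na * len(b) / 2
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), na):
        total += 1
        if abs(u_stat(idx) - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_identical_samples_midpoint_u(self):
        u, _ = mann_whitney_u([1, 2], [1, 2])
        assert u == 2.0

    def test_complete_separation_exact_p(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 / C(6,3)

    def test_agrees_with_permutation_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            na, nb = rng.integers(3, 6, size=2)
            a = rng.normal(size=na)
            b = rng.normal(size=nb)
            _, p = mann_whitney_u(a, b)
            assert abs(p - _exact_mw_p(a, b)) < 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestLifespanSummary:
    def test_identical_cohorts_zero_change(self):
        out = lifespan_summary(np.array([10, 20, 30]),
                               np.array([10, 20, 30]))
        assert out["pct_change_mean"] == 0.0
        assert out["mann_whitney_p"] > 0.9

    def test_forty_percent_reduction_exact(self):
        out = lifespan_summary(np.array([10, 10]), np.array([6, 6]))
        assert out["pct_change_mean"] == pytest.approx(-40.0)
        assert out["pct_change_median"] == pytest.approx(-40.0)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            lifespan_summary(np.array([0, 0]), np.array([1, 2]))
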