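"""Lifespan and single-cell trajectory statistics.

These are the quantification procedures used on mother-cell time-lapse data
(simulated or real): interdivision-time series, ensembles aligned at the
last budding event with 95% confidence limits of the mean, right-censored
survival curves, senescence-entry-point (SEP) detection, logistic models for
event odds within a follow-up window, and Mann–Whitney pairwise comparisons.

All statistics are order-invariant over the traces in a cohort.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .engine import CohortSummary, LineageTrace

__all__ = [
    "AlignedEnsemble",
    "LogisticFit",
    "interdivision_times",
    "align_last_budding",
    "survival_curve",
    "detect_sep",
    "logistic_event_model",
    "mann_whitney_u",
    "lifespan_summary",
]


@dataclass
class AlignedEnsemble:
    """Per-cell observable matrix aligned at the last budding event.

    ``rel_time`` is minutes relative to the final budding (0 = last budding);
    ``values`` is (n_cells, n_timepoints) with NaN outside each cell's span.
    """

    observable: str
    rel_time: np.ndarray
    values: np.ndarray
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rel_time_min": self.rel_time,
            "mean": self.mean,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n": self.n,
        })


@dataclass
class LogisticFit:
    intercept: float
    slope: float
    odds_ratio: float
    or_ci: tuple[float, float]
    unit: float = 1.0
    separation: bool = False
    n: int = 0
    predictor_grid: np.ndarray = field(default=None, repr=False)
    fitted_probability: np.ndarray = field(default=None, repr=False)

    def predict(self, x: np.ndarray) -> np.ndarray:
        z = self.intercept + self.slope * np.asarray(x, dtype=float)
        return 1.0 / (1.0 + np.exp(-z))


# --------------------------------------------------------------------------
# interdivision times and alignment
# --------------------------------------------------------------------------

def interdivision_times(trace: LineageTrace) -> pd.DataFrame:
    """Durations between consecutive budding events, one row per generation.

    Returns columns ``generation`` (1-based index of the completed cycle)
    and ``duration_min``; empty for traces with fewer than two buddings.
    """
    buds = trace.budding_times
    if len(buds) < 2:
        return pd.DataFrame(columns=["generation", "duration_min"])
    durations = np.diff(buds)
    return pd.DataFrame({
        "generation": np.arange(1, len(durations) + 1),
        "duration_min": durations,
    })


def _mean_ci(values: np.ndarray, level: float = 0.95):
    """Mean and Student-t confidence limits along axis 0, NaN-aware."""
    n = np.sum(np.isfinite(values), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(values, axis=0)
        sd = np.nanstd(values, axis=0, ddof=1)
    half = np.full_like(mean, np.nan)
    ok = n >= 2
    tcrit = stats.t.ppf(0.5 + level / 2, np.maximum(n - 1, 1))
    half[ok] = tcrit[ok] * sd[ok] / np.sqrt(n[ok])
    half[n == 1] = 0.0
    return mean, mean - half, mean + half, n


def align_last_budding(
    cohort: CohortSummary | list[LineageTrace],
    observable: str,
    level: float = 0.95,
    method: str = "t",
    n_boot: int = 1000,
    seed: int = 0,
) -> AlignedEnsemble:
    """Align traces so each cell's final budding event sits at t = 0.

    The observable is linearly interpolated onto a common grid with the
    cohort's sampling spacing; the mean and its confidence limits are
    computed per time point over the cells present there.  ``method="t"``
    uses Student-t limits of the mean; ``method="bootstrap"`` resamples
    cells (percentile interval), preferable for skewed observables.
    """
    traces = cohort.traces if isinstance(cohort, CohortSummary) else cohort
    if not traces:
        raise ValueError("empty cohort")
    for tr in traces:
        if observable not in tr.samples.columns:
            raise KeyError(f"observable {observable!r} not in trace columns")
        if len(tr.budding_times) == 0:
            raise ValueError("every trace must contain at least one budding")
    dt = float(np.median(np.diff(traces[0].samples["time_min"]))) \
        if len(traces[0].samples) > 1 else 10.0
    lo = min(tr.samples["time_min"].iloc[0] - tr.budding_times[-1]
             for tr in traces)
    hi = max(tr.samples["time_min"].iloc[-1] - tr.budding_times[-1]
             for tr in traces)
    grid = np.arange(math.floor(lo / dt) * dt, hi + dt / 2, dt)
    mat = np.full((len(traces), len(grid)), np.nan)
    for i, tr in enumerate(traces):
        t_rel = tr.samples["time_min"].to_numpy() - tr.budding_times[-1]
        v = tr.samples[observable].to_numpy(dtype=float)
        inside = (grid >= t_rel[0] - 1e-9) & (grid <= t_rel[-1] + 1e-9)
        mat[i, inside] = np.interp(grid[inside], t_rel, v)
    if method == "t":
        mean, lo_ci, hi_ci, n = _mean_ci(mat, level)
    elif method == "bootstrap":
        n = np.sum(np.isfinite(mat), axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            mean = np.nanmean(mat, axis=0)
            rng = np.random.default_rng(seed)
            boots = np.empty((n_boot, mat.shape[1]))
            for b in range(n_boot):
                idx = rng.integers(0, mat.shape[0], size=mat.shape[0])
                boots[b] = np.nanmean(mat[idx], axis=0)
            alpha = (1.0 - level) / 2
            lo_ci = np.nanquantile(boots, alpha, axis=0)
            hi_ci = np.nanquantile(boots, 1.0 - alpha, axis=0)
    else:
        raise ValueError("method must be 't' or 'bootstrap'")
    return AlignedEnsemble(
        observable=observable, rel_time=grid, values=mat,
        mean=mean, ci_low=lo_ci, ci_high=hi_ci, n=n,
    )


# --------------------------------------------------------------------------
# survival
# --------------------------------------------------------------------------

def survival_curve(
    lifespans: np.ndarray,
    censored: np.ndarray | None = None,
) -> pd.DataFrame:
    """Right-censored survival S(g) = P(lifespan > g) over generations.

    Kaplan–Meier estimate; with no censoring this is the empirical fraction
    of cells with lifespan strictly greater than g.  Returns a step table
    with one row per generation 0..max.
    """
    lifespans = np.asarray(lifespans)
    if lifespans.size == 0:
        raise ValueError("empty lifespan vector")
    if np.any(lifespans < 0):
        raise ValueError("lifespans must be >= 0")
    if censored is None:
        censored = np.zeros(len(lifespans), dtype=bool)
    censored = np.asarray(censored, dtype=bool)
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter()
    km.fit(lifespans, event_observed=~censored)
    gens = np.arange(0, int(lifespans.max()) + 1)
    surv = km.survival_function_at_times(gens).to_numpy()
    return pd.DataFrame({"generation": gens, "survival": surv})


def survival_at(curve: pd.DataFrame, g: float) -> float:
    """S(g) from a survival table (step function, right-continuous)."""
    below = curve[curve["generation"] <= g]
    return float(below["survival"].iloc[-1]) if len(below) else 1.0


# --------------------------------------------------------------------------
# senescence entry point
# --------------------------------------------------------------------------

def detect_sep(
    durations: np.ndarray | pd.DataFrame,
    n_sd: float = 3.0,
    min_sustained: int = 2,
) -> int | None:
    """Detect the senescence entry point in an interdivision-time series.

    The SEP is the first generation whose duration exceeds
    mean(young) + ``n_sd``*SD(young) — young being the first half of the
    series — with every subsequent duration also above that threshold (a
    sustained, abrupt slowdown maintained until death).  A single final
    outlier is not senescence: the sustained run must span at least
    ``min_sustained`` generations.  Returns the 1-based generation index,
    or None if the series never crosses or is too short (< 5 generations).
    """
    if isinstance(durations, pd.DataFrame):
        durations = durations["duration_min"].to_numpy()
    durations = np.asarray(durations, dtype=float)
    if len(durations) < 5:
        warnings.warn("series too short for SEP detection (< 5 generations)")
        return None
    young = durations[: len(durations) // 2]
    thr = young.mean() + n_sd * young.std(ddof=0)
    above = durations > thr
    # first index from which exceedance is sustained to the end
    sustained = np.logical_and.accumulate(above[::-1])[::-1]
    idx = np.nonzero(sustained)[0]
    if idx.size == 0 or len(durations) - idx[0] < min_sustained:
        return None
    return int(idx[0]) + 1


# --------------------------------------------------------------------------
# logistic event model
# --------------------------------------------------------------------------

def logistic_event_model(
    predictor: np.ndarray,
    outcome: np.ndarray,
    unit: float = 1.0,
    window_min: float = 180.0,
    level: float = 0.95,
) -> LogisticFit:
    """Maximum-likelihood logistic regression of a binary event on a reading.

    ``outcome`` marks whether the event occurred within the follow-up window
    (``window_min`` is metadata recording that window).  The odds ratio is
    reported per ``unit`` of the predictor with a Wald confidence interval.
    Perfect separation is flagged rather than raised.
    """
    import statsmodels.api as sm

    x = np.asarray(predictor, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    X = sm.add_constant(x)
    separation = False
    params = bse = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            params = np.asarray(res.params)
            bse = np.asarray(res.bse)
            if not np.all(np.isfinite(bse)) or np.any(np.abs(params) > 50):
                separation = True
        except Exception:
            separation = True
        if params is None:
            # report a ridge-stabilized point estimate; the OR is unbounded
            try:
                res = sm.Logit(y, X).fit_regularized(
                    disp=0, alpha=1e-4, maxiter=500)
                params = np.asarray(res.params)
            except Exception:
                params = np.array([0.0, 0.0])
            bse = np.full(2, np.inf)
    intercept, slope = float(params[0]), float(params[1])
    zcrit = stats.norm.ppf(0.5 + level / 2)
    orr = math.exp(min(slope * unit, 700.0))
    if separation or not np.isfinite(bse[1]):
        ci = (0.0, math.inf)
        separation = True
    else:
        half = zcrit * bse[1] * unit
        ci = (math.exp(slope * unit - half), math.exp(slope * unit + half))
    grid = np.linspace(x.min(), x.max(), 100)
    fit = LogisticFit(
        intercept=intercept, slope=slope, odds_ratio=orr, or_ci=ci,
        unit=unit, separation=separation, n=len(y), predictor_grid=grid,
        fitted_probability=None,
    )
    fit.fitted_probability = fit.predict(grid)
    return fit


# --------------------------------------------------------------------------
# pairwise comparisons
# --------------------------------------------------------------------------

def mann_whitney_u(
    sample_a: np.ndarray, sample_b: np.ndarray
) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test with mid-rank tie handling.

    Exact null distribution for small samples (n_a + n_b <= 16, no ties),
    normal approximation with tie-corrected variance otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    small = a.size + b.size <= 16
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def lifespan_summary(
    cohort_a: CohortSummary | np.ndarray,
    cohort_b: CohortSummary | np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> dict:
    """Percent change in mean/median lifespan of B relative to A, with a
    Mann–Whitney p-value and a bootstrap CI on the mean percent change."""
    a = cohort_a.lifespans if isinstance(cohort_a, CohortSummary) else \
        np.asarray(cohort_a)
    b = cohort_b.lifespans if isinstance(cohort_b, CohortSummary) else \
        np.asarray(cohort_b)
    if a.size < 2 or b.size < 2:
        raise ValueError("cohorts must contain at least 2 lifespans each")
    if a.mean() == 0:
        raise ValueError("reference cohort has zero mean lifespan")
    pct_mean = 100.0 * (b.mean() - a.mean()) / a.mean()
    med_a = np.median(a)
    pct_median = 100.0 * (np.median(b) - med_a) / med_a if med_a else math.nan
    _, p = mann_whitney_u(a, b)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        ra = rng.choice(a, size=a.size, replace=True)
        rb = rng.choice(b, size=b.size, replace=True)
        boots[i] = 100.0 * (rb.mean() - ra.mean()) / ra.mean()
    alpha = (1.0 - level) / 2
    ci = tuple(np.quantile(boots, [alpha, 1.0 - alpha]))
    return {
        "pct_change_mean": pct_mean,
        "pct_change_median": pct_median,
        "mann_whitney_p": p,
        "pct_change_mean_ci": ci,
        "n_a": int(a.size),
        "n_b": int(b.size),
    }
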