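"""Shared fixtures: the calibrated network and memoized scenario cohorts.

Cohorts are expensive (75 stochastic lineages each), so one session-scoped
factory computes each scenario at most once and shares it across tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from chaperostart.engine import run_cohort
from chaperostart.network import build_wildtype_network

#: fixed seeds per scenario so every run of the suite sees the same cohorts
_SCENARIO_SEEDS = {
    "wt": 101, "cln3": 102, "whi5": 103, "ydj1": 104, "oCLN3": 105,
    "oSSA1YDJ1": 106, "fast_growth": 107, "large_v0": 108, "PFD": 109,
    "CD": 110, "PFD+oCLN3": 111, "ydj1+oCLN3": 112, "slow_growth": 113,
    "small_v0": 114, "x2_7CHP": 115,
}

COHORT_N = 75


@pytest.fixture(scope="session")
def wt_network():
    return build_wildtype_network()


@pytest.fixture(scope="session")
def cohort(wt_network):
    """Memoized cohort factory: cohort('cln3') -> CohortSummary (n=75)."""
    cache = {}

    def get(name: str, keep_traces: bool = False):
        key = (name, keep_traces)
        if key not in cache:
            # a traceful cohort also serves requests without traces
            if (name, True) in cache:
                return cache[(name, True)]
            cache[key] = run_cohort(
                wt_network, scenario=name, n=COHORT_N,
                seed=_SCENARIO_SEEDS[name], keep_traces=keep_traces,
            )
        return cache[key]

    return get


@pytest.fixture(scope="session")
def wt_cohort(cohort):
    """Wild-type cohort with full traces (aligned-trajectory tests)."""
    return cohort("wt", keep_traces=True)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
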