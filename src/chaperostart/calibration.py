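"""Calibration constraints, parameter scanning and sensitivity analysis.

The calibrated model must exhibit, in a deterministic young cell: ~10000
Ssa1/Ydj1 chaperones, ~1000 Whi5 molecules at G1 start and ~100 Cln3
molecules (mean over the first G1), keep the folded-protein pool under
10^5 molecules, and give a mean stochastic wild-type replicative lifespan
of ~30 cycles.  ``parameter_scan`` screens candidate parameter sets with
the cheap deterministic constraints first and runs the stochastic lifespan
check only for survivors; ``sensitivity_analysis`` perturbs one parameter
by ±1/10/25% and reports the lifespan response, which is how the shipped
mutant scenario grades were chosen.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import run_cohort, simulate_deterministic
from .network import (
    CHAPERONE_MOIETY,
    ParameterSet,
    ReactionNetwork,
    build_wildtype_network,
)

__all__ = [
    "Constraint",
    "ConstraintReport",
    "constraint_check",
    "parameter_scan",
    "sensitivity_analysis",
    "deterministic_lifespan",
]

#: calibration targets (value, relative tolerance)
CHAPERONE_TARGET = (10_000.0, 0.10)
WHI5_TARGET = (1_000.0, 0.10)
CLN3_TARGET = (100.0, 0.25)
LIFESPAN_TARGET = 30.0


@dataclass
class Constraint:
    name: str
    target: float
    observed: float
    passed: bool
    tolerance: float | None = None


@dataclass
class ConstraintReport:
    constraints: list[Constraint] = field(default_factory=list)

    @property
    def overall(self) -> bool:
        return all(c.passed for c in self.constraints)

    def residual(self) -> float:
        """Sum of relative deviations from the targets (ranking key)."""
        out = 0.0
        for c in self.constraints:
            if c.target:
                out += abs(c.observed - c.target) / abs(c.target)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(c) for c in self.constraints])

    def __getitem__(self, name: str) -> Constraint:
        for c in self.constraints:
            if c.name == name:
                return c
        raise KeyError(name)


def _chaperone_moiety_total(row: Mapping[str, float]) -> float:
    return sum(row.get(sp, 0.0) * units
               for sp, units in CHAPERONE_MOIETY.items())


def deterministic_young_cycle(
    network: ReactionNetwork, n_generations: int = 10
) -> pd.DataFrame:
    """Deterministic trajectory over the first young-cell cycles."""
    p = network.parameters
    t_end = n_generations * (p.budded_duration + 30.0)
    return simulate_deterministic(network, t_end=t_end)


def constraint_check(
    network: ReactionNetwork | None = None,
    params: ParameterSet | None = None,
    check_lifespan: bool = True,
    n: int | None = None,
    seed: int = 0,
    det_generations: int = 10,
) -> ConstraintReport:
    """Evaluate the calibration constraints for a parameter set.

    Deterministic constraints (molecule numbers, folded cap) are always
    evaluated; the stochastic lifespan constraint (cohort mean within its
    95% CL of 30) runs when ``check_lifespan`` is set.
    """
    if network is None:
        network = build_wildtype_network(params)
    p = network.parameters
    traj = deterministic_young_cycle(network, det_generations)
    report = ConstraintReport()

    row0 = traj.iloc[0]
    chap = _chaperone_moiety_total(row0)
    tgt, tol = CHAPERONE_TARGET
    report.constraints.append(Constraint(
        "chaperone_total", tgt, chap, abs(chap - tgt) <= tol * tgt, tol))

    whi5 = float(row0.get("Whi5a", 0.0) + row0.get("Whi5i", 0.0)
                 + row0.get("CW", 0.0))
    tgt, tol = WHI5_TARGET
    report.constraints.append(Constraint(
        "whi5_g1_start", tgt, whi5, abs(whi5 - tgt) <= tol * tgt, tol))

    first_g1 = traj[(traj["generation"] == 0) & (traj["phase"] == "G1")]
    if len(first_g1) == 0:
        first_g1 = traj.iloc[:1]
    cln3 = float((first_g1["Cln3c"] + first_g1["Cln3n"]
                  + first_g1.get("CW", 0.0)).mean())
    tgt, tol = CLN3_TARGET
    report.constraints.append(Constraint(
        "cln3_mean_g1", tgt, cln3, abs(cln3 - tgt) <= tol * tgt, tol))

    protf_max = float(traj["ProtF"].max())
    cap = p.folded_cap_target
    report.constraints.append(Constraint(
        "folded_pool_cap", cap, protf_max, protf_max <= cap, None))

    if check_lifespan:
        cohort = run_cohort(network, n=n or p.cohort_size, seed=seed,
                            keep_traces=False)
        lo, hi = cohort.lifespan_ci()
        report.constraints.append(Constraint(
            "wt_mean_lifespan", LIFESPAN_TARGET, cohort.mean_lifespan,
            lo <= LIFESPAN_TARGET <= hi, None))
    return report


def parameter_scan(
    grid: Mapping[str, Sequence[float]] | Iterable[ParameterSet],
    base: ParameterSet | None = None,
    check_lifespan: bool = False,
    n: int = 25,
    seed: int = 0,
) -> pd.DataFrame:
    """Screen candidate parameter sets against the calibration constraints.

    ``grid`` is either a mapping of parameter name -> values (full factorial
    over the base set) or an iterable of explicit :class:`ParameterSet`.
    Deterministic screening runs first; the stochastic lifespan stage (with
    a fixed seed) runs only for deterministic survivors.  Returns all
    candidates ranked by constraint residual, with a ``feasible`` flag; the
    nearest misses rank first when the feasible set is empty.
    """
    base = base or ParameterSet()
    if isinstance(grid, Mapping):
        import itertools

        keys = list(grid)
        candidates = []
        for combo in itertools.product(*(grid[k] for k in keys)):
            p = copy.deepcopy(base)
            for k, v in zip(keys, combo):
                if not hasattr(p, k):
                    raise KeyError(f"unknown parameter {k!r}")
                setattr(p, k, v)
            candidates.append((dict(zip(keys, combo)), p))
    else:
        candidates = [({}, p) for p in grid]
    rows = []
    for label, p in candidates:
        rep = constraint_check(params=p, check_lifespan=False)
        feasible_det = rep.overall
        feasible = feasible_det
        mean_ls = np.nan
        if feasible_det and check_lifespan:
            net = build_wildtype_network(p)
            cohort = run_cohort(net, n=n, seed=seed, keep_traces=False)
            lo, hi = cohort.lifespan_ci()
            mean_ls = cohort.mean_lifespan
            feasible = lo <= LIFESPAN_TARGET <= hi
        rows.append({
            **label,
            "residual": rep.residual(),
            "feasible_deterministic": feasible_det,
            "feasible": feasible,
            "mean_lifespan": mean_ls,
            "params": p,
        })
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["feasible", "residual"], ascending=[False, True]
    ).reset_index(drop=True)


def deterministic_lifespan(network: ReactionNetwork,
                           t_end: float | None = None) -> int:
    """Budding count of the deterministic (fluid-limit) lineage."""
    p = network.parameters
    if t_end is None:
        t_end = p.max_generations * (p.budded_duration + 40.0)
    traj = simulate_deterministic(network, t_end=t_end)
    return sum(1 for _, e in traj.attrs["events"] if e == "budding")


def sensitivity_analysis(
    network: ReactionNetwork,
    parameter: str,
    deltas: Sequence[float] = (-0.25, -0.10, -0.01, 0.0, 0.01, 0.10, 0.25),
    n: int = 75,
    seed: int = 0,
    stochastic: bool = True,
) -> pd.DataFrame:
    """Lifespan response to relative perturbations of one parameter.

    For each delta the parameter is multiplied by (1 + delta); the table
    reports the deterministic lifespan proxy and (optionally) the mean
    stochastic lifespan over ``n`` lineages with a fixed seed block shared
    across deltas, so delta = 0 reproduces the baseline exactly.
    """
    p0 = network.parameters
    if not hasattr(p0, parameter):
        raise KeyError(f"unknown parameter {parameter!r}")
    seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)
    rows = []
    for d in deltas:
        p = copy.deepcopy(p0)
        setattr(p, parameter, getattr(p0, parameter) * (1.0 + d))
        net = build_wildtype_network(p)
        det = deterministic_lifespan(net)
        row = {"delta": d, "value": getattr(p, parameter),
               "deterministic_lifespan": det}
        if stochastic:
            cohort = run_cohort(net, n=n, seeds=seeds, keep_traces=False)
            row["mean_lifespan"] = cohort.mean_lifespan
            row["median_lifespan"] = cohort.median_lifespan
        rows.append(row)
    return pd.DataFrame(rows)
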