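"""Reaction network for the chaperone–Start aging model.

The model couples two modules through a single pool of Hsp70/Hsp40 chaperones
(Ssa1/Ydj1, lumped as ``Chap``):

* a protein folding/aggregation pathway — folded protein (``ProtF``) misfolds
  into monomers (``ProtM``) that dimerize into a pool of non-nucleated
  oligomers (``Agg2``) and nucleate into hexamers (``Agg6``, the nucleated
  pool).  Chaperones bind misfolded species 1:1 per protein unit
  (``C1``/``C2``/``C6`` complexes), refold or degrade small species, and hand
  nucleated aggregates to the Hsp104 disaggregase.  Nucleated aggregates grow
  autocatalytically by templating conversion of oligomers.
* a minimal Start module — cyclin Cln3 is synthesized as a precursor
  (``Cln3c``) and requires free chaperone to reach its active nuclear form
  (``Cln3n``), which inactivates the Whi5 inhibitor (``Whi5a`` -> ``Whi5i``).
  Start fires when 75% of the G1-entry Whi5 molecules are inactivated.

All reactions are count-based mass action; every catalyst appears with equal
stoichiometry on both sides.  Volume convention: zero-order synthesis is
volume-coupled (rate ∝ V), first-order reactions are volume-independent, and
every multi-molecular reaction scales as 1/V.  The lumped aggregation and
binding steps of order > 2 stand for sequences of encounters in which the
first collision is rate-limiting, so they inherit the bimolecular 1/V
dilution rather than the dilute-gas 1/V^(m-1) law (which would switch the
high-order nucleation steps off entirely in grown mothers).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, fields
from typing import Mapping

import numpy as np

__all__ = [
    "SpeciesDef",
    "ReactionDef",
    "ParameterSet",
    "PerturbationScenario",
    "ReactionNetwork",
    "NetworkConfigError",
    "ScenarioLookupError",
    "build_wildtype_network",
    "apply_perturbation",
    "propensity",
    "hsp104_supply_rate",
    "wildtype_initial_counts",
    "SCENARIOS",
    "get_scenario",
    "compose_scenarios",
]


class NetworkConfigError(ValueError):
    """Invalid parameter or network construction input."""


class ScenarioLookupError(KeyError):
    """Unknown scenario name or perturbation target."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

SPECIES_ROLES = {
    "folded_protein",
    "misfolded_monomer",
    "dimer_pool",
    "hexamer_pool",
    "free_chaperone",
    "chaperone_monomer_complex",
    "chaperone_dimer_complex",
    "chaperone_hexamer_complex",
    "disaggregase",
    "cyclin_precursor",
    "cyclin_nuclear",
    "whi5_active",
    "whi5_inactive",
    "cyclin_whi5_complex",
    "chaperone_adsorbed",
    "proteotoxic_substrate",
}


@dataclass(frozen=True)
class SpeciesDef:
    name: str
    role: str
    initial_count: int = 0

    def __post_init__(self) -> None:
        if self.role not in SPECIES_ROLES:
            raise NetworkConfigError(f"unknown species role: {self.role!r}")
        if self.initial_count < 0:
            raise NetworkConfigError(
                f"species {self.name!r}: initial_count must be >= 0"
            )


@dataclass(frozen=True)
class ReactionDef:
    """A mass-action reaction with integer stoichiometry.

    ``rate_constant`` names a field of :class:`ParameterSet`; the numeric
    value is resolved when the network is compiled for simulation.
    """

    name: str
    reactants: Mapping[str, int]
    products: Mapping[str, int]
    rate_constant: str
    #: override the default volume scaling (None = use volume_exponent(order));
    #: e.g. 0 for volume-independent synthesis of a translation-limited protein
    volume_exponent_override: int | None = None

    def __post_init__(self) -> None:
        for coeff in (*self.reactants.values(), *self.products.values()):
            if coeff < 1:
                raise NetworkConfigError(
                    f"reaction {self.name!r}: stoichiometries must be >= 1"
                )

    @property
    def order(self) -> int:
        """Total reactant stoichiometry (molecularity)."""
        return sum(self.reactants.values())

    @property
    def vol_exponent(self) -> int:
        if self.volume_exponent_override is not None:
            return self.volume_exponent_override
        return volume_exponent(self.order)

    def net_change(self) -> dict[str, int]:
        net: dict[str, int] = {}
        for sp, coeff in self.products.items():
            net[sp] = net.get(sp, 0) + coeff
        for sp, coeff in self.reactants.items():
            net[sp] = net.get(sp, 0) - coeff
        return {sp: c for sp, c in net.items() if c != 0}


@dataclass
class ParameterSet:
    """Calibrated model parameters (time in minutes, volume in fL).

    Rate constants are in stochastic (count-based) units at unit volume; the
    engine applies the V^(1-m) volume scaling.  The defaults are the shipped
    calibrated set: they place ~10^4 chaperones, ~10^3 Whi5 and ~10^2 Cln3
    molecules in a young cell, keep the folded pool under ``folded_cap_target``
    and give a mean wild-type replicative lifespan of ~30 cycles.
    """

    # protein synthesis / turnover / misfolding
    k_syn_protf: float = 1.5          # molecules/fL/min, volume-coupled
    k_deg_protf: float = 2.167e-3     # 1/min, raised so folded pool <= cap
    k_misfold: float = 4.5e-3         # 1/min

    # aggregation
    k_dimerize: float = 0.03          # 2 ProtM -> Agg2
    k_nucleate: float = 1.5e-3        # 3 Agg2 -> Agg6 (primary)
    k_template: float = 0.01          # Agg6 + 3 Agg2 -> 2 Agg6 (templated)

    # chaperone binding (1:1 chaperone per protein unit)
    k_bind1: float = 0.04             # Chap + ProtM -> C1
    k_bind2: float = 6.0e-7           # 2 Chap + Agg2 -> C2
    k_bind6: float = 4.4e-20          # 6 Chap + Agg6 -> C6

    # refolding / degradation of held substrate
    k_refold1: float = 0.24           # C1 -> Chap + ProtF
    k_refold2: float = 0.1            # C2 -> 2 Chap + 2 ProtF
    k_deg_bound: float = 0.06         # C1 -> Chap

    # aggregation of chaperone-held substrate (recruitment channel)
    k_coalesce: float = 1.5e-3        # 2 C1 -> C2
    k_nucleate_held: float = 2.0e-3   # 3 C2 -> Agg6 + 6 Chap
    k_template_held: float = 6.0e-3   # C6 + 3 C2 -> C6 + Agg6 + 6 Chap
    k_recruit: float = 0.025          # C6 + 2 ProtM -> C6 + Agg2
    k_adsorb: float = 8.0e-5          # Agg6 + Chap -> Agg6 + CB (surface trap)

    # Hsp104 disaggregase
    k_hsp_basal: float = 6.67e-2      # 0 -> Hsp104, volume-coupled
    k_hsp_induced: float = 2.0e-3     # C6 -> C6 + Hsp104
    k_hsp_turnover: float = 1.0e-2    # Hsp104 -> 0
    k_disagg: float = 3.0e-5          # C6 + Hsp104 -> Hsp104 + 6 C1

    # Start module
    k_cln3_syn: float = 25.0          # 0 -> Cln3c, translation-limited
    k_cln3_act: float = 1.0e-2        # Cln3c + Chap -> Cln3n + Chap
    k_cln3_deg: float = 0.25          # all Cln3 forms, incl. in complex
    k_whi5_bind: float = 0.25         # Cln3n + Whi5a -> CW
    k_whi5_cat: float = 1.6           # CW -> Cln3n + Whi5i
    k_whi5_inact: float = 1.0e-4      # Whi5a + Cln3n -> Whi5i + Cln3n (direct)

    # proteotoxic substrate (only wired in when a scenario adds it)
    k_pfd_syn: float = 0.35           # 0 -> PFD, volume-coupled
    k_pfd_conv: float = 0.2           # PFD -> ProtM (constitutively misfolded)
    k_cd_deg: float = 0.02            # CD -> 0 (inert control turnover)

    # cell-cycle / geometry
    start_threshold_fraction: float = 0.75
    budded_duration: float = 75.0     # min
    growth_rate: float = 2.75e-3      # 1/min, G1 growth of the mother
    initial_volume: float = 30.0      # fL
    v_max: float = 150.0              # fL, growth saturates in deep arrest
    daughter_fraction: float = 0.2    # soluble-pool share leaving with the bud
    whi5_init_concentration: float = 1000.0 / 30.0  # molecules/fL
    chap_total: float = 10000.0       # total chaperone moiety, molecules
    max_generations: int = 75
    growth_cv: float = 0.12           # per-lineage CV of the growth rate
    v0_cv: float = 0.12               # per-lineage CV of the birth volume
    arrest_timeout: float = 900.0     # min, ~10 young generation times
    folded_cap_target: float = 1.0e5  # molecules
    cohort_size: int = 75
    sampling_interval: float = 10.0   # min

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name.startswith("k_") and v < 0:
                raise NetworkConfigError(f"rate {f.name} must be >= 0, got {v}")
        if not 0.0 < self.start_threshold_fraction < 1.0:
            raise NetworkConfigError(
                "start_threshold_fraction must be in (0, 1), got "
                f"{self.start_threshold_fraction}"
            )
        if self.max_generations < 1:
            raise NetworkConfigError("max_generations must be >= 1")
        for name in ("budded_duration", "initial_volume", "v_max",
                     "arrest_timeout", "sampling_interval", "chap_total"):
            if getattr(self, name) <= 0:
                raise NetworkConfigError(f"{name} must be > 0")
        if not 0.0 < self.daughter_fraction < 1.0:
            raise NetworkConfigError("daughter_fraction must be in (0, 1)")


@dataclass(frozen=True)
class PerturbationScenario:
    """Named multiplicative parameter modifications (a genotype/condition).

    ``modifications`` maps ParameterSet field names to multipliers (> 0).
    ``substrate`` optionally wires in a second substrate species: an
    aggregation-prone one (``"aggregating"``, the PFD construct) feeding the
    shared aggregate pools, or an inert one (``"inert"``, the scrambled CD
    control).
    """

    name: str
    modifications: Mapping[str, float] = field(default_factory=dict)
    substrate: str | None = None

    def __post_init__(self) -> None:
        for target, mult in self.modifications.items():
            if mult <= 0:
                raise NetworkConfigError(
                    f"scenario {self.name!r}: multiplier for {target!r} "
                    "must be > 0"
                )
        if self.substrate not in (None, "aggregating", "inert"):
            raise NetworkConfigError(
                f"scenario {self.name!r}: substrate must be 'aggregating', "
                "'inert' or None"
            )


@dataclass
class ReactionNetwork:
    species: list[SpeciesDef]
    reactions: list[ReactionDef]
    parameters: ParameterSet
    # moiety maps: units of conserved moiety carried by each species
    chaperone_moiety: dict[str, int] = field(default_factory=dict)
    protein_moiety: dict[str, int] = field(default_factory=dict)
    # reactions exempt from the corresponding conservation law
    chaperone_exempt: frozenset[str] = frozenset()
    protein_exempt: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise NetworkConfigError("species names must be unique")
        known = set(names)
        for r in self.reactions:
            for sp in (*r.reactants, *r.products):
                if sp not in known:
                    raise NetworkConfigError(
                        f"reaction {r.name!r} references unknown species {sp!r}"
                    )
            if not hasattr(self.parameters, r.rate_constant):
                raise NetworkConfigError(
                    f"reaction {r.name!r} references unknown rate "
                    f"{r.rate_constant!r}"
                )

    # -- indexing helpers ---------------------------------------------------
    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def species_index(self, name: str) -> int:
        return self.species_names.index(name)

    def initial_counts(self) -> np.ndarray:
        return np.array([s.initial_count for s in self.species], dtype=np.int64)

    def rate_values(self) -> np.ndarray:
        return np.array(
            [getattr(self.parameters, r.rate_constant) for r in self.reactions],
            dtype=np.float64,
        )

    def stoichiometry(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(reactant_stoich, net_change, order) matrices for the engine."""
        ns, nr = len(self.species), len(self.reactions)
        idx = {s.name: i for i, s in enumerate(self.species)}
        react = np.zeros((nr, ns), dtype=np.int64)
        net = np.zeros((nr, ns), dtype=np.int64)
        for j, r in enumerate(self.reactions):
            for sp, c in r.reactants.items():
                react[j, idx[sp]] = c
            for sp, c in r.net_change().items():
                net[j, idx[sp]] = c
        order = react.sum(axis=1)
        return react, net, order

    def moiety_net_change(self, moiety: Mapping[str, int]) -> dict[str, int]:
        """Net change of a conserved moiety per reaction (symbolic check)."""
        out = {}
        for r in self.reactions:
            out[r.name] = sum(
                c * moiety.get(sp, 0) for sp, c in r.net_change().items()
            )
        return out

    def check_conservation(self) -> None:
        """Assert the declared moiety maps are consistent with the reactions."""
        for moiety, exempt, label in (
            (self.chaperone_moiety, self.chaperone_exempt, "chaperone"),
            (self.protein_moiety, self.protein_exempt, "protein"),
        ):
            if not moiety:
                continue
            for rname, d in self.moiety_net_change(moiety).items():
                if d != 0 and rname not in exempt:
                    raise NetworkConfigError(
                        f"reaction {rname!r} changes the {label} moiety by {d} "
                        "but is not declared exempt"
                    )


# --------------------------------------------------------------------------
# Wild-type construction
# --------------------------------------------------------------------------

def wildtype_initial_counts(params: ParameterSet) -> dict[str, int]:
    """Young-cell initial counts at the deterministic cycle-start steady state.

    Closed-form quasi-steady-state values of the calibrated young cell
    (aggregate pools empty, chaperone mostly free).  Using the steady state as
    the initial condition makes the young-cell molecule numbers both inputs
    and outputs of the calibration.
    """
    p = params
    V = p.initial_volume
    protf = p.k_syn_protf * V / (p.k_deg_protf + p.k_misfold)
    flux = p.k_misfold * protf                        # misfolding flux, 1/min
    c1 = flux / (p.k_refold1 + p.k_deg_bound)
    c2 = (p.k_coalesce * c1 * c1 / 2.0 / V) / p.k_refold2
    chap_free = p.chap_total - c1 - 2.0 * c2
    capture = p.k_bind1 * chap_free / V
    protm = flux / capture if capture > 0 else 0.0
    hsp104 = p.k_hsp_basal * V / p.k_hsp_turnover
    act = p.k_cln3_act * chap_free / V                # activation rate, 1/min
    cln3c = p.k_cln3_syn / (p.k_cln3_deg + act)
    n_nuc = act * cln3c / p.k_cln3_deg                # nuclear cyclin, free+CW
    whi5a = round(p.whi5_init_concentration * V)
    bindw = p.k_whi5_bind * whi5a / V
    cw = n_nuc * bindw / (bindw + p.k_whi5_cat + p.k_cln3_deg)
    cln3n = n_nuc - cw
    return {
        "ProtF": round(protf),
        "ProtM": round(protm),
        "Agg2": 0,
        "Agg6": 0,
        "Chap": round(chap_free),
        "C1": round(c1),
        "C2": round(c2),
        "C6": 0,
        "Hsp104": round(hsp104),
        "Cln3c": round(cln3c),
        "Cln3n": round(cln3n),
        "CW": round(cw),
        "CB": 0,
        "Whi5a": max(1, int(whi5a)),
        "Whi5i": 0,
    }


_ROLES = {
    "ProtF": "folded_protein",
    "ProtM": "misfolded_monomer",
    "Agg2": "dimer_pool",
    "Agg6": "hexamer_pool",
    "Chap": "free_chaperone",
    "C1": "chaperone_monomer_complex",
    "C2": "chaperone_dimer_complex",
    "C6": "chaperone_hexamer_complex",
    "Hsp104": "disaggregase",
    "Cln3c": "cyclin_precursor",
    "Cln3n": "cyclin_nuclear",
    "CW": "cyclin_whi5_complex",
    "CB": "chaperone_adsorbed",
    "Whi5a": "whi5_active",
    "Whi5i": "whi5_inactive",
}

CHAPERONE_MOIETY = {"Chap": 1, "C1": 1, "C2": 2, "C6": 6, "CB": 1}
PROTEIN_MOIETY = {
    "ProtF": 1, "ProtM": 1, "Agg2": 2, "Agg6": 6,
    "C1": 1, "C2": 2, "C6": 6, "PFD": 1,
}

# reactions allowed to change the protein moiety: synthesis, degradation
_PROTEIN_EXEMPT = frozenset(
    {"syn_protf", "deg_protf", "deg_bound", "syn_pfd"}
)
# no chaperone synthesis/degradation reactions exist; nothing is exempt
_CHAPERONE_EXEMPT: frozenset[str] = frozenset()


def _wildtype_reactions() -> list[ReactionDef]:
    R = ReactionDef
    return [
        R("syn_protf", {}, {"ProtF": 1}, "k_syn_protf"),
        R("deg_protf", {"ProtF": 1}, {}, "k_deg_protf"),
        R("misfold", {"ProtF": 1}, {"ProtM": 1}, "k_misfold"),
        R("dimerize", {"ProtM": 2}, {"Agg2": 1}, "k_dimerize"),
        R("nucleate_primary", {"Agg2": 3}, {"Agg6": 1}, "k_nucleate"),
        R("nucleate_templated", {"Agg6": 1, "Agg2": 3}, {"Agg6": 2},
          "k_template"),
        R("bind_monomer", {"Chap": 1, "ProtM": 1}, {"C1": 1}, "k_bind1"),
        R("bind_dimer", {"Chap": 2, "Agg2": 1}, {"C2": 1}, "k_bind2"),
        R("bind_hexamer", {"Chap": 6, "Agg6": 1}, {"C6": 1}, "k_bind6"),
        R("refold_monomer", {"C1": 1}, {"Chap": 1, "ProtF": 1}, "k_refold1"),
        R("refold_dimer", {"C2": 1}, {"Chap": 2, "ProtF": 2}, "k_refold2"),
        R("deg_bound", {"C1": 1}, {"Chap": 1}, "k_deg_bound"),
        R("coalesce_held", {"C1": 2}, {"C2": 1}, "k_coalesce"),
        R("nucleate_held", {"C2": 3}, {"Agg6": 1, "Chap": 6},
          "k_nucleate_held"),
        R("template_held", {"C6": 1, "C2": 3}, {"C6": 1, "Agg6": 1, "Chap": 6},
          "k_template_held"),
        R("recruit_monomer", {"C6": 1, "ProtM": 2}, {"C6": 1, "Agg2": 1},
          "k_recruit"),
        R("recruit_free", {"Agg6": 1, "ProtM": 2}, {"Agg6": 1, "Agg2": 1},
          "k_recruit"),
        R("adsorb_free", {"Agg6": 1, "Chap": 1}, {"Agg6": 1, "CB": 1},
          "k_adsorb"),
        R("adsorb_coated", {"C6": 1, "Chap": 1}, {"C6": 1, "CB": 1},
          "k_adsorb"),
        R("disaggregate", {"C6": 1, "Hsp104": 1}, {"Hsp104": 1, "C1": 6},
          "k_disagg"),
        R("hsp104_basal", {}, {"Hsp104": 1}, "k_hsp_basal"),
        R("hsp104_induced", {"C6": 1}, {"C6": 1, "Hsp104": 1},
          "k_hsp_induced"),
        R("hsp104_turnover", {"Hsp104": 1}, {}, "k_hsp_turnover"),
        R("cln3_synthesis", {}, {"Cln3c": 1}, "k_cln3_syn",
          volume_exponent_override=0),
        R("cln3_activation", {"Cln3c": 1, "Chap": 1}, {"Cln3n": 1, "Chap": 1},
          "k_cln3_act"),
        R("cln3_deg_cyto", {"Cln3c": 1}, {}, "k_cln3_deg"),
        R("cln3_deg_nuc", {"Cln3n": 1}, {}, "k_cln3_deg"),
        R("whi5_bind", {"Whi5a": 1, "Cln3n": 1}, {"CW": 1}, "k_whi5_bind"),
        R("whi5_cat", {"CW": 1}, {"Cln3n": 1, "Whi5i": 1}, "k_whi5_cat"),
        R("cw_decay", {"CW": 1}, {"Whi5a": 1}, "k_cln3_deg"),
        R("whi5_inactivation", {"Whi5a": 1, "Cln3n": 1},
          {"Whi5i": 1, "Cln3n": 1}, "k_whi5_inact"),
    ]


def build_wildtype_network(
    params: ParameterSet | None = None,
    substrate: str | None = None,
) -> ReactionNetwork:
    """Assemble the calibrated wild-type network.

    ``substrate`` optionally adds a second substrate species: the
    aggregation-prone PFD (synthesized, then joining the misfolded-monomer
    pool and hence the shared aggregate pools) or the inert CD control.
    """
    params = ParameterSet() if params is None else params
    params.validate()
    init = wildtype_initial_counts(params)
    species = [
        SpeciesDef(name, _ROLES[name], init[name]) for name in _ROLES
    ]
    reactions = _wildtype_reactions()
    protein_exempt = set(_PROTEIN_EXEMPT)
    if substrate == "aggregating":
        species.append(SpeciesDef("PFD", "proteotoxic_substrate", 0))
        reactions.append(ReactionDef("syn_pfd", {}, {"PFD": 1}, "k_pfd_syn"))
        reactions.append(
            ReactionDef("pfd_misfold", {"PFD": 1}, {"ProtM": 1}, "k_pfd_conv")
        )
    elif substrate == "inert":
        species.append(SpeciesDef("CD", "proteotoxic_substrate", 0))
        reactions.append(ReactionDef("syn_cd", {}, {"CD": 1}, "k_pfd_syn"))
        reactions.append(ReactionDef("deg_cd", {"CD": 1}, {}, "k_cd_deg"))
        protein_exempt |= {"syn_cd", "deg_cd"}
    elif substrate is not None:
        raise NetworkConfigError(f"unknown substrate kind: {substrate!r}")
    net = ReactionNetwork(
        species=species,
        reactions=reactions,
        parameters=params,
        chaperone_moiety=dict(CHAPERONE_MOIETY),
        protein_moiety=dict(PROTEIN_MOIETY),
        chaperone_exempt=_CHAPERONE_EXEMPT,
        protein_exempt=frozenset(protein_exempt),
    )
    net.check_conservation()
    return net


# --------------------------------------------------------------------------
# Perturbation scenarios
# --------------------------------------------------------------------------

# Shipped scenario ledger.  Multipliers were selected by the sensitivity
# protocol in :mod:`chaperostart.calibration`: deterministic {±1, ±10, ±25}%
# scans plus deletion-grade reductions and overexpression grades; the smallest
# scanned perturbation reproducing the qualitative mutant phenotype is kept.
SCENARIOS: dict[str, PerturbationScenario] = {
    "wt": PerturbationScenario("wt"),
    "cln3": PerturbationScenario("cln3", {"k_cln3_syn": 0.5}),
    "whi5": PerturbationScenario("whi5", {"whi5_init_concentration": 0.5}),
    "ydj1": PerturbationScenario("ydj1", {"chap_total": 0.25}),
    "oCLN3": PerturbationScenario("oCLN3", {"k_cln3_syn": 3.0}),
    "oSSA1YDJ1": PerturbationScenario("oSSA1YDJ1", {"chap_total": 1.5}),
    "x2_7CHP": PerturbationScenario(
        "x2_7CHP", {"chap_total": 2.0, "k_hsp_basal": 2.0}
    ),
    "fast_growth": PerturbationScenario("fast_growth", {"growth_rate": 1.25}),
    "slow_growth": PerturbationScenario("slow_growth", {"growth_rate": 0.8}),
    "large_v0": PerturbationScenario("large_v0", {"initial_volume": 1.5}),
    "small_v0": PerturbationScenario("small_v0", {"initial_volume": 0.67}),
    "PFD": PerturbationScenario("PFD", substrate="aggregating"),
    "CD": PerturbationScenario("CD", substrate="inert"),
}


def compose_scenarios(*scenarios: PerturbationScenario) -> PerturbationScenario:
    """Multiplicative, order-independent composition of scenarios."""
    mods: dict[str, float] = {}
    substrate: str | None = None
    for sc in scenarios:
        for target, mult in sc.modifications.items():
            mods[target] = mods.get(target, 1.0) * mult
        if sc.substrate is not None:
            if substrate is not None and substrate != sc.substrate:
                raise NetworkConfigError(
                    "cannot compose scenarios with conflicting substrates"
                )
            substrate = sc.substrate
    name = "+".join(sc.name for sc in scenarios)
    return PerturbationScenario(name, mods, substrate)


def get_scenario(name: str) -> PerturbationScenario:
    """Look up a scenario, supporting '+'-compositions (e.g. 'ydj1+oCLN3')."""
    if name in SCENARIOS:
        return SCENARIOS[name]
    if "+" in name:
        parts = [p.strip() for p in name.split("+")]
        try:
            return compose_scenarios(*(SCENARIOS[p] for p in parts))
        except KeyError as exc:
            raise ScenarioLookupError(
                f"unknown scenario {exc.args[0]!r}; valid names: "
                f"{sorted(SCENARIOS)}"
            ) from None
    raise ScenarioLookupError(
        f"unknown scenario {name!r}; valid names: {sorted(SCENARIOS)}"
    )


def apply_perturbation(
    network: ReactionNetwork, scenario: PerturbationScenario | str
) -> ReactionNetwork:
    """Return a new network with the scenario's multipliers applied.

    The input network is never mutated.  Initial counts are re-derived from
    the perturbed parameters, so e.g. a chaperone-dosage scenario also scales
    the young-cell chaperone pool.
    """
    if isinstance(scenario, str):
        scenario = get_scenario(scenario)
    params = copy.deepcopy(network.parameters)
    for target, mult in scenario.modifications.items():
        if not hasattr(params, target):
            raise ScenarioLookupError(
                f"scenario {scenario.name!r}: unknown target {target!r}; "
                f"valid targets are ParameterSet fields"
            )
        setattr(params, target, getattr(params, target) * mult)
    existing = {s.name for s in network.species}
    substrate = scenario.substrate
    if substrate is None and "PFD" in existing:
        substrate = "aggregating"
    elif substrate is None and "CD" in existing:
        substrate = "inert"
    return build_wildtype_network(params, substrate=substrate)


# --------------------------------------------------------------------------
# Propensities
# --------------------------------------------------------------------------

def volume_exponent(order: int) -> int:
    """Volume scaling exponent of a mass-action reaction of given order.

    Synthesis (order 0) is volume-coupled (∝ V); first-order reactions are
    volume-independent; all multi-molecular reactions dilute as 1/V
    (encounter-limited convention, see module docstring).
    """
    if order == 0:
        return 1
    if order == 1:
        return 0
    return -1


def _combinations(n: int, s: int) -> float:
    """C(n, s) for small s (distinct unordered reactant tuples)."""
    if n < s:
        return 0.0
    out = 1.0
    for i in range(s):
        out *= (n - i)
    return out / math.factorial(s)


def propensity(
    reaction: ReactionDef,
    state: Mapping[str, int],
    volume: float,
    rate: float | None = None,
    params: ParameterSet | None = None,
) -> float:
    """Stochastic mass-action propensity of ``reaction`` in ``state``.

    Combinatorial counting for repeated reactants (k*C(n,2) for 2X -> ...),
    with the volume scaling of :func:`volume_exponent`: synthesis is
    volume-coupled, multi-molecular collisions dilute as 1/V.
    """
    if rate is None:
        if params is None:
            raise ValueError("provide either rate or params")
        rate = getattr(params, reaction.rate_constant)
    a = rate * volume ** reaction.vol_exponent
    for sp, s in reaction.reactants.items():
        n = state[sp]
        if n < 0:
            raise ValueError(
                f"negative count for {sp!r} in reaction {reaction.name!r}"
            )
        a *= _combinations(n, s)
    return a


def hsp104_supply_rate(
    state: Mapping[str, int], params: ParameterSet, volume: float | None = None
) -> float:
    """Total Hsp104 synthesis rate: basal (volume-coupled) + induced by C6."""
    V = params.initial_volume if volume is None else volume
    return params.k_hsp_basal * V + params.k_hsp_induced * state.get("C6", 0)


# --------------------------------------------------------------------------
# Config serialization
# --------------------------------------------------------------------------

def params_to_dict(params: ParameterSet) -> dict:
    return {f.name: getattr(params, f.name) for f in fields(params)}


def params_from_dict(d: Mapping) -> ParameterSet:
    p = ParameterSet()
    for key, value in d.items():
        if not hasattr(p, key):
            raise NetworkConfigError(f"unknown parameter key {key!r}")
        setattr(p, key, type(getattr(p, key))(value))
    p.validate()
    return p


def save_config(params: ParameterSet, path) -> None:
    """Write a ParameterSet as a YAML config file."""
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump({"parameters": params_to_dict(params)}, fh,
                       sort_keys=True)


def load_config(path) -> ParameterSet:
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return params_from_dict(doc.get("parameters", doc))


def load_scenario_ledger(path=None) -> dict[str, PerturbationScenario]:
    """Load a scenario ledger from YAML (default: the shipped ledger)."""
    import yaml

    if path is None:
        from importlib.resources import files

        text = (files("chaperostart") / "data" / "scenarios.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    out = {}
    for name, entry in doc["scenarios"].items():
        entry = entry or {}
        out[name] = PerturbationScenario(
            name=name,
            modifications=entry.get("modifications", {}) or {},
            substrate=entry.get("substrate"),
        )
    return out
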