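"""Stochastic engine: SSA correctness, events, determinism."""

import numpy as np
import pytest
from scipy import stats

from chaperostart.engine import (
    run_cohort,
    run_lineage,
    simulate_deterministic,
    simulate_ssa,
)
from chaperostart.network import (
    ParameterSet,
    ReactionDef,
    ReactionNetwork,
    SpeciesDef,
)


def toy_network(species, reactions, **params):
    params.setdefault("growth_rate", 0.0)
    params.setdefault("initial_volume", 1.0)
    return ReactionNetwork(
        species=species, reactions=reactions,
        parameters=ParameterSet(**params),
    )


class TestSSABasics:
    def test_zero_reactions_counts_constant_volume_grows(self):
        net = toy_network(
            [SpeciesDef("A", "folded_protein", 7)], [],
            growth_rate=0.01, initial_volume=2.0, v_max=1e9,
        )
        tr = simulate_ssa(net, t_end=100.0, seed=3, cycle_events=False)
        assert (tr.samples["A"] == 7).all()
        t = tr.samples["time_min"].to_numpy()
        np.testing.assert_allclose(
            tr.samples["volume_fL"], 2.0 * np.exp(0.01 * t), rtol=1e-9)

    def test_pure_death_ensemble_mean_matches_analytic(self):
        # dA/dt = -k A  =>  E[A(10)] = 100 * exp(-1)
        net = toy_network(
            [SpeciesDef("A", "folded_protein", 100)],
            [ReactionDef("death", {"A": 1}, {}, "k_deg_protf")],
            k_deg_protf=0.1,
        )
        finals = np.array([
            simulate_ssa(net, t_end=10.0, seed=s,
                         cycle_events=False).samples["A"].iloc[-1]
            for s in range(500)
        ])
        expected = 100.0 * np.exp(-1.0)
        se = finals.std(ddof=1) / np.sqrt(len(finals))
        tcrit = stats.t.ppf(0.995, len(finals) - 1)
        assert abs(finals.mean() - expected) < tcrit * se + 1e-9

    def test_same_seed_bit_identical(self, wt_network):
        a = simulate_ssa(wt_network, t_end=300.0, seed=11)
        b = simulate_ssa(wt_network, t_end=300.0, seed=11)
        assert a.events == b.events
        assert a.samples.equals(b.samples)

    def test_t_end_must_exceed_start(self, wt_network):
        with pytest.raises(ValueError):
            simulate_ssa(wt_network, t_end=-1.0, seed=0)


class TestSSAvsCME:
    def test_stationary_distribution_matches_master_equation(self):
        # birth/death/pair-annihilation toy: 0 -> X, X -> 0, 2X -> 0
        ks, kd, k2, cap = 0.6, 0.05, 0.005, 60
        net = toy_network(
            [SpeciesDef("X", "folded_protein", 0)],
            [ReactionDef("syn", {}, {"X": 1}, "k_syn_protf"),
             ReactionDef("deg", {"X": 1}, {}, "k_deg_protf"),
             ReactionDef("ann", {"X": 2}, {}, "k_dimerize")],
            k_syn_protf=ks, k_deg_protf=kd, k_dimerize=k2,
        )
        # exact stationary law from the truncated chemical master equation
        Q = np.zeros((cap + 1, cap + 1))
        for n in range(cap + 1):
            if n < cap:
                Q[n, n + 1] = ks
            if n >= 1:
                Q[n, n - 1] += kd * n
            if n >= 2:
                Q[n, n - 2] += k2 * n * (n - 1) / 2
            Q[n, n] = -Q[n].sum()
        w, v = np.linalg.eig(Q.T)
        pi = np.real(v[:, np.argmin(np.abs(w))])
        pi = np.abs(pi) / np.abs(pi).sum()
        tr = simulate_ssa(net, t_end=1.2e6, seed=7, cycle_events=False)
        x = tr.samples["X"].to_numpy()[500::3]  # burn-in, thin to ~30 min
        emp = np.bincount(x, minlength=cap + 1)[: cap + 1] / len(x)
        tv = 0.5 * np.abs(emp - pi).sum()
        assert tv < 0.02
        assert x.max() <= 30  # stays a small-copy-number system

    def test_linear_network_ssa_mean_matches_ode(self):
        # moment equations are exact for first-order networks
        species = [SpeciesDef("X", "folded_protein", 0),
                   SpeciesDef("Y", "misfolded_monomer", 0)]
        reactions = [
            ReactionDef("syn", {}, {"X": 1}, "k_syn_protf"),
            ReactionDef("conv", {"X": 1}, {"Y": 1}, "k_misfold"),
            ReactionDef("deg", {"Y": 1}, {}, "k_deg_protf"),
        ]
        net = toy_network(species, reactions, k_syn_protf=2.0,
                          k_misfold=0.05, k_deg_protf=0.02)
        ode = simulate_deterministic(net, t_end=200.0, cycle_events=False)
        checkpoints = [20.0, 60.0, 100.0, 150.0, 200.0]
        ens = np.array([
            simulate_ssa(net, t_end=200.0, seed=s,
                         cycle_events=False).samples
            .set_index("time_min").loc[checkpoints, "Y"].to_numpy()
            for s in range(400)
        ])
        ode_y = ode.set_index("time_min").loc[checkpoints, "Y"].to_numpy()
        mean = ens.mean(axis=0)
        se = ens.std(axis=0, ddof=1) / np.sqrt(ens.shape[0])
        tcrit = stats.t.ppf(0.975, ens.shape[0] - 1)
        assert np.all(np.abs(mean - ode_y) < tcrit * se + 1e-9)


def start_toy_network(**overrides):
    """Minimal Start module: Cln3n inactivates Whi5, no other reactions."""
    params = dict(
        k_whi5_inact=0.5, growth_rate=0.0, initial_volume=30.0,
        budded_duration=150.0, arrest_timeout=1e5,
        whi5_init_concentration=1000.0 / 30.0, max_generations=10,
    )
    params.update(overrides)
    species = [
        SpeciesDef("Whi5a", "whi5_active", 1000),
        SpeciesDef("Whi5i", "whi5_inactive", 0),
        SpeciesDef("Cln3n", "cyclin_nuclear", 1),
        SpeciesDef("Agg6", "hexamer_pool", 12),
        SpeciesDef("ProtF", "folded_protein", 10000),
    ]
    reactions = [ReactionDef(
        "inact", {"Whi5a": 1, "Cln3n": 1}, {"Whi5i": 1, "Cln3n": 1},
        "k_whi5_inact")]
    return toy_network(species, reactions, **params)


class TestCellCycleEvents:
    def test_start_fires_exactly_at_75_percent_inactivation(self):
        # Whi5a + Whi5i = 1000 throughout; Start must fire at the jump where
        # active Whi5 reaches 250 (>= 75% of the G1-entry count inactivated)
        net = start_toy_network()
        tr = simulate_ssa(net, t_end=140.0, seed=5, cycle_events=True)
        assert len(tr.budding_times) >= 1
        t_bud = tr.budding_times[0]
        df = tr.samples
        pre = df[df["time_min"] < t_bud]
        post = df[df["time_min"] >= t_bud]
        assert (pre["Whi5a"] >= 251).all()   # threshold not yet reached
        assert post["Whi5a"].iloc[0] <= 250  # and reached exactly at Start
        assert (pre["Whi5i"] <= 749).all()
        assert post["Whi5i"].iloc[0] >= 750

    def test_no_inactivation_source_censors_without_budding(self):
        net = start_toy_network()
        net.species[2] = SpeciesDef("Cln3n", "cyclin_nuclear", 0)
        tr = simulate_ssa(net, t_end=500.0, seed=5, cycle_events=True)
        assert tr.lifespan == 0
        assert tr.censored

    def test_division_resets_and_retains(self):
        net = start_toy_network()
        tr = simulate_ssa(net, t_end=400.0, seed=9, cycle_events=True)
        assert len(tr.division_times) >= 1
        t_div = tr.division_times[0]
        df = tr.samples
        post = df[df["time_min"] >= t_div].iloc[0]
        pre = df[df["time_min"] < t_div].iloc[-1]
        assert post["Cln3n"] == 0            # nuclear cyclin cleared
        assert post["Agg6"] == 12            # aggregates fully retained
        assert post["Whi5a"] == 1000         # reset to same concentration
        assert post["generation"] == pre["generation"] + 1
        # soluble pool partitioned binomially with the bud's volume share
        assert post["ProtF"] < 10000
        assert 7600 <= post["ProtF"] <= 8400

    def test_buddings_and_divisions_alternate(self, wt_cohort):
        for tr in wt_cohort.traces[:20]:
            kinds = [e for _, e in tr.events if e in ("budding", "division")]
            assert kinds[::2] == ["budding"] * len(kinds[::2])
            assert kinds[1::2] == ["division"] * len(kinds[1::2])
            assert tr.lifespan == kinds.count("budding")

    def test_lifespan_counts_buddings(self, wt_cohort):
        for tr in wt_cohort.traces:
            assert tr.lifespan == len(tr.budding_times)


class TestLineageAndCohort:
    def test_no_aggregation_reaches_generation_cap_censored(self):
        p = ParameterSet(
            k_dimerize=0.0, k_nucleate=0.0, k_template=0.0, k_coalesce=0.0,
            k_nucleate_held=0.0, k_template_held=0.0, k_recruit=0.0,
            k_adsorb=0.0, k_bind6=0.0, max_generations=6,
        )
        from chaperostart.network import build_wildtype_network

        net = build_wildtype_network(p)
        tr = run_lineage(net, seed=2, heterogeneity=False)
        assert tr.lifespan == 6
        assert tr.censored

    def test_fixed_seed_block_reproducible(self, wt_network):
        a = run_cohort(wt_network, n=3, seeds=[5, 6, 7], keep_traces=False)
        b = run_cohort(wt_network, n=3, seeds=[5, 6, 7], keep_traces=False)
        np.testing.assert_array_equal(a.lifespans, b.lifespans)

    def test_cohort_size_minimum(self, wt_network):
        with pytest.raises(ValueError):
            run_cohort(wt_network, n=1)

    def test_chaperone_moiety_conserved_along_trajectory(self, wt_cohort):
        # no chaperone synthesis/degradation exists, so the moiety total is
        # exactly constant along every sampled trajectory
        for tr in wt_cohort.traces[:10]:
            df = tr.samples
            total = (df["Chap"] + df["C1"] + 2 * df["C2"] + 6 * df["C6"]
                     + df["CB"])
            assert total.nunique() == 1

    def test_hsp104_rises_over_lifetime(self, wt_cohort):
        rising = 0
        for tr in wt_cohort.traces:
            h = tr.samples["Hsp104"].to_numpy()
            q = max(len(h) // 4, 1)
            if h[-q:].mean() > h[:q].mean():
                rising += 1
        assert rising >= 0.8 * len(wt_cohort.traces)


class TestDeterministic:
    def test_linear_steady_state_closed_form(self):
        net = toy_network(
            [SpeciesDef("X", "folded_protein", 0)],
            [ReactionDef("syn", {}, {"X": 1}, "k_syn_protf"),
             ReactionDef("deg", {"X": 1}, {}, "k_deg_protf")],
            k_syn_protf=3.0, k_deg_protf=0.05,
        )
        traj = simulate_deterministic(net, t_end=600.0, cycle_events=False)
        assert traj["X"].iloc[-1] == pytest.approx(60.0, rel=1e-6)

    def test_wildtype_deterministic_keeps_folded_pool_capped(
        self, wt_network
    ):
        traj = simulate_deterministic(wt_network, t_end=1500.0)
        assert traj["ProtF"].max() <= \
            wt_network.parameters.folded_cap_target
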