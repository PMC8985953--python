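"""Motif composition: autoregulation, mutual repression, perturbations."""

import numpy as np
import pytest

from chromem import (DimensionlessParams, PerturbationEvent, StopCondition,
                     apply_events_ssa, build_network, find_equilibria,
                     make_autoregulated, make_mutual_repression, reduce_to_1d,
                     robustness_scan, simulate_ode, ssa_run)
from chromem.ode import relax_to_steady_state
from chromem.circuits import with_coefficients


class TestAutoregulated:
    def test_zero_gain_reduces_to_open_loop(self, small_params):
        gc = make_autoregulated(small_params, p_x=0.0)
        open_net = build_network(small_params)
        # QSS network identical to the open loop
        assert len(gc.qss_network.reactions) == len(open_net.reactions)
        n = open_net.state_array({"D12R": 8})
        assert np.allclose(gc.qss_network.propensities(n),
                           open_net.propensities(n))

    def test_qss_equals_boosted_autocatalysis(self, small_params):
        """Under protein QSS the closed loop is the open loop with the
        activating auto-catalysis raised by u_tilde_A * p_x."""
        gc = make_autoregulated(small_params, p_x=2.0, u_tilde_A=0.5)
        qss = gc.qss_network
        x = np.array([0.2, 0.3, 0.1, 0.2, 0.2])  # D, DA, D1R, D2R, D12R
        rhs_qss = qss.mean_field(x)
        boosted = build_network(small_params)
        rhs_open = boosted.mean_field(x)
        # the difference is exactly the extra drive (0.5*2) * DA * D on DA
        extra = 0.5 * 2.0 * x[qss.index("DA")] * x[qss.index("D")]
        assert rhs_qss[qss.index("DA")] - rhs_open[qss.index("DA")] == \
            pytest.approx(extra)
        assert rhs_qss[qss.index("D")] - rhs_open[qss.index("D")] == \
            pytest.approx(-extra)

    def test_qss_matches_fast_protein_ode(self, base_params):
        p = base_params.replace(eps=0.15, mu_prime=0.5)
        fast = make_autoregulated(p, p_x=2.0, gamma_x_bar=200.0)
        qss = make_autoregulated(p, p_x=2.0).qss_network
        init = {"DA": 0.5, "D1R": 0.1, "D2R": 0.1, "D12R": 0.1}
        tq = simulate_ode(qss, init, 50.0, t_eval=np.linspace(0, 50, 51))
        tf = simulate_ode(fast.network, dict(init, X=1.0), 50.0,
                          t_eval=np.linspace(0, 50, 51))
        cols = ("DA", "D1R", "D2R", "D12R")
        dq = tq.states[:, [qss.index(s) for s in cols]]
        df = tf.states[:, [fast.network.index(s) for s in cols]]
        assert np.max(np.abs(dq - df)) < 1e-2

    def test_bifurcation_in_p_x(self, base_params):
        """Growing autoregulation turns the repressed-monostable circuit
        bistable (the active state becomes a stable equilibrium)."""
        p = base_params.replace(eps=0.15, mu_prime=0.5)
        counts = []
        for px in (0.0, 4.0):
            net = make_autoregulated(p, p_x=px).qss_network
            counts.append(len(find_equilibria(net, n_starts=50,
                                              seed=2).stable))
        assert counts == [1, 2]

    def test_hill_coupling_requires_parameters(self, small_params):
        with pytest.raises(ValueError):
            make_autoregulated(small_params, p_x=1.0, coupling="hill")
        gc = make_autoregulated(small_params, p_x=1.0, coupling="hill",
                                hill=(0.5, 2.0))
        labels = {r.label: r for r in gc.network.reactions}
        assert labels["A<-X"].hill == (0.5, 2.0)

    def test_reduced_chain_monotone_in_p_x(self, small_params):
        """Active-state stationary mass and active-state memory time both
        increase strictly with the autoregulation gain."""
        p = small_params.replace(eps=0.1, eps_prime=0.5, mu_prime=0.5)
        pi0, tauA = [], []
        for px in (0.0, 1.0, 5.0):
            chain = reduce_to_1d(make_autoregulated(p, p_x=px).qss_network,
                                 warn_regime=False)
            pi0.append(chain.stationary()[0])
            tauA.append(chain.mfpt_to_top())
        assert pi0[0] < pi0[1] < pi0[2]
        assert tauA[0] < tauA[1] < tauA[2]


class TestMutualRepression:
    def test_decoupled_at_zero_gain(self, small_params):
        gc = make_mutual_repression(small_params, p_x=0.0, p_z=0.0)
        # QSS network: no cross-coupling reactions remain
        cross = [r for r in gc.qss_network.reactions if "(qss)" in r.label]
        assert cross == []

    def test_composition_is_two_genes_plus_coupling(self, small_params):
        """The reaction set is exactly two autoregulated gene copies plus
        the cross-repression drives, nothing else."""
        gc = make_mutual_repression(small_params, p_x=1.0)
        single = make_autoregulated(small_params, p_x=1.0).network
        per_gene = len(single.reactions)
        cross = [r for r in gc.network.reactions
                 if r.label.endswith("<-Z") or r.label.endswith("<-X")]
        # the self-activation drives also use the <-X/<-Z naming
        self_acts = [r for r in cross if r.label.startswith("A<-")]
        pure_cross = len(cross) - len(self_acts)
        assert pure_cross == 8  # 4 repressive drive reactions per gene
        assert len(gc.network.reactions) == 2 * per_gene + pure_cross

    def test_conservation_per_gene(self, small_params):
        gc = make_mutual_repression(small_params, p_x=2.0)
        net = gc.network
        run = ssa_run(net, {"DA:X": 8, "D:Z": 8, "X": 4}, 20.0, seed=5,
                      sample_times=np.linspace(1, 20, 20))
        for grp in net.conserved_groups:
            idx = [net.index(s) for s in grp]
            assert np.all(run.samples[:, idx].sum(axis=1) == 8)

    def test_pattern_census_vs_p(self):
        """Low protein production: both genes off.  High production with
        slow erasure: two exclusive one-on/one-off patterns."""
        from chromem import stationary_histogram
        p = DimensionlessParams(eps=0.2, mu_prime=0.6, u0A=0.1, u10R=0.1,
                                u20R=0.1, D_tot=20)

        def census(px):
            gc = make_mutual_repression(p, p_x=px)
            net = gc.network
            init = [{"DA:X": 20, "D:Z": 20, "X": int(px * 20)},
                    {"D:X": 20, "DA:Z": 20, "Z": int(px * 20)}]
            dist = stationary_histogram(net, init, horizon=400.0, reps=16,
                                        seed=3, samples_per_rep=100)
            iX, iZ = net.index("DA:X"), net.index("DA:Z")
            m = dict(offoff=0.0, excl=0.0, onon=0.0)
            for s, pr in zip(dist.states, dist.probs):
                on_x, on_z = s[iX] >= 15, s[iZ] >= 15
                off_x, off_z = s[iX] <= 5, s[iZ] <= 5
                if off_x and off_z:
                    m["offoff"] += pr
                elif (on_x and off_z) or (off_x and on_z):
                    m["excl"] += pr
                elif on_x and on_z:
                    m["onon"] += pr
            return m

        low = census(0.05)
        high = census(5.0)
        assert low["offoff"] > 0.9
        assert high["excl"] > 0.8 and high["offoff"] < 0.05

    def test_deterministic_pattern_equilibria(self):
        """QSS ODE: two mirror-image one-on/one-off equilibria at high
        protein production, plus both-off when erasure is slow."""
        p = DimensionlessParams(eps=0.2, mu_prime=0.6, u0A=0.1, u10R=0.1,
                                u20R=0.1, D_tot=20)
        net = make_mutual_repression(p, p_x=5.0).qss_network
        es = find_equilibria(net, n_starts=60, seed=4)
        states = [(e.value(net, "DA:X"), e.value(net, "DA:Z"))
                  for e in es.stable]
        assert any(a > 0.7 and b < 0.2 for a, b in states)
        assert any(a < 0.2 and b > 0.7 for a, b in states)


class TestPerturbations:
    def test_reset_on_empty_protein_is_noop(self, small_params):
        """Resetting an already-empty protein does not perturb the path
        (compared against a coefficient-preserving dummy event with the
        same segmentation, so the random streams coincide)."""
        gc = make_autoregulated(small_params, p_x=1.0)
        net = gc.network
        coeff = {r.label: r.coefficient for r in net.reactions}["0+1"]
        ev1 = [PerturbationEvent(5.0, "reset_protein_to_zero", "X")]
        ev2 = [PerturbationEvent(5.0, "set_input", "0+1", coeff)]
        r1 = apply_events_ssa(net, {"D12R": 8, "X": 0}, 10.0, 7, ev1)
        r2 = apply_events_ssa(net, {"D12R": 8, "X": 0}, 10.0, 7, ev2)
        assert np.array_equal(r1.state_end, r2.state_end)

    def test_unknown_target_rejected(self, small_params):
        gc = make_autoregulated(small_params, p_x=1.0)
        ev = [PerturbationEvent(1.0, "reset_protein_to_zero", "Znope")]
        with pytest.raises(ValueError):
            apply_events_ssa(gc.network, {"D12R": 8, "X": 0}, 10.0, 7, ev)

    def test_set_input_changes_dynamics(self, small_params):
        net = build_network(small_params)
        ev = [PerturbationEvent(5.0, "set_input", "0+1", 50.0)]
        run = apply_events_ssa(net, {"D12R": 8}, 40.0, 11, ev,
                               sample_times=np.linspace(0, 39.9, 40))
        nA = run.samples[:, net.index("DA")]
        assert nA[-1] > 4  # the huge activating drive takes over

    def test_ode_resets_recoverable_at_small_eps(self):
        """Deterministic version of the TF-reset protocol: with slow basal
        erasure the active chromatin state recovers after each protein
        reset, so autoregulated expression survives transient TF removal."""
        from chromem import apply_events_ode
        p = DimensionlessParams(eps=0.05, mu_prime=0.5, u0A=0.1, u10R=0.1,
                                u20R=0.1, D_tot=50)
        net = make_autoregulated(p, p_x=2.0).network
        ev = [PerturbationEvent(t, "reset_protein_to_zero", "X")
              for t in (30.0, 60.0)]
        tr = apply_events_ode(net, {"DA": 0.9, "D1R": 0.0, "D2R": 0.0,
                                    "D12R": 0.1, "X": 1.8}, 100.0, ev)
        assert tr.states[-1, net.index("DA")] > 0.9
        # the reset is visible: X drops to zero right after each event
        jX = net.index("X")
        # the sample grid holds both boundary states at t = 30: the last
        # pre-reset sample and the first post-reset one
        i = np.searchsorted(tr.t, 30.0, side="right") - 1
        assert tr.states[i, jX] == 0.0
        assert tr.states[i - 1, jX] > 0.5

    def test_active_state_survives_resets_at_small_eps(self):
        """With slow basal erasure the chromatin state carries the memory
        through repeated removals of the activating TF."""
        def survival(eps):
            p = DimensionlessParams(eps=eps, mu_prime=0.6, u0A=0.1,
                                    u10R=0.1, u20R=0.1, D_tot=20)
            gc = make_mutual_repression(p, p_x=5.0, gamma_bar=0.3)
            net = gc.network
            events = [PerturbationEvent(float(t), "reset_protein_to_zero", sp)
                      for t in np.arange(10.0, 150.0, 10.0)
                      for sp in ("X", "Z")]
            seeds = np.random.SeedSequence(9).generate_state(24) >> 1
            kept = 0
            for s in seeds:
                run = apply_events_ssa(net, {"DA:X": 20, "D:Z": 20, "X": 100},
                                       150.0, int(s), events)
                n = run.state_end
                if (n[net.index("DA:X")] >= 15
                        and n[net.index("DA:Z")] <= 5):
                    kept += 1
            return kept / 24

        assert survival(0.3) > survival(1.0)


class TestRobustness:
    def test_critical_uR_increases_with_p_x(self, base_params):
        p = base_params.replace(eps=0.1, mu_prime=0.7)
        _, crit = robustness_scan(p, np.linspace(0, 3, 13), [0.0, 1.0, 3.0])
        assert crit[0.0] < crit[1.0] < crit[3.0]

    def test_zero_gain_matches_open_loop_characteristic(self, base_params):
        p = base_params.replace(eps=0.3, mu_prime=0.7)
        df, _ = robustness_scan(p, [0.0, 0.5], [0.0])
        open_net = build_network(p.with_inputs(u1R=0.5, u2R=0.5))
        x = relax_to_steady_state(
            open_net, relax_to_steady_state(
                build_network(p), {"DA": 1.0, "D1R": 0.0, "D2R": 0.0,
                                   "D12R": 0.0}))
        got = df[(df.p_x == 0.0) & (df.uR == 0.5)].DA.iloc[0]
        assert got == pytest.approx(x[open_net.index("DA")], abs=1e-6)


def test_with_coefficients_rejects_unknown_label(full_net_small):
    with pytest.raises(ValueError):
        with_coefficients(full_net_small, {"nope": 1.0})
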