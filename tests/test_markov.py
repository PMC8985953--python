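"""Exact CME analysis: generator, stationary law, MFPT, reduction, limits."""

import numpy as np
import pytest
import scipy.sparse as sp

from chromem import (DimensionlessParams, ReducedChain, StateSpace,
                     build_generator, build_network, exact_mfpt,
                     exact_stationary, limit_mfpt_active,
                     limit_mfpt_active_autoregulated, limit_mfpt_repressed,
                     limit_stationary, reduce_to_1d)
from chromem.markov import _compositions


class TestStateSpace:
    def test_size_full_variant(self, full_net_small):
        space = StateSpace(full_net_small)
        from math import comb
        assert len(space) == comb(8 + 4, 4)  # 495

    def test_bijective_indexing(self, full_net_small):
        space = StateSpace(full_net_small)
        for i in (0, 17, 311, len(space) - 1):
            assert space.index(space.states[i]) == i

    def test_rejects_unbounded_species(self, small_params):
        from chromem import make_autoregulated
        gc = make_autoregulated(small_params, p_x=1.0)
        with pytest.raises(ValueError):
            StateSpace(gc.network)  # explicit protein is unbounded


class TestGenerator:
    def test_zero_coefficients_give_zero_generator(self):
        p = DimensionlessParams(eps=0.0, eps_prime=0.0, alpha=0.0,
                                alpha_bar=0.0, alpha_prime=0.0, D_tot=4)
        net = build_network(p, overrides={"4": 0.0})
        Q = build_generator(net)
        assert Q.nnz == 0

    def test_rows_sum_to_zero(self, full_net_small):
        Q = build_generator(full_net_small)
        assert np.max(np.abs(np.asarray(Q.sum(axis=1)))) < 1e-12
        off_diag = Q - sp.diags(Q.diagonal())
        assert off_diag.min() >= 0.0

    def test_histone_only_dtot2_hand_computed(self):
        """All 6x6 generator entries match independent hand-written
        propensity arithmetic for the 3-species circuit at D_tot = 2."""
        uA, u2, al, eps, epsp, mu = 0.1, 0.2, 2.0, 0.3, 0.5, 0.7
        p = DimensionlessParams(alpha=al, eps=eps, eps_prime=epsp, mu=mu,
                                u0A=uA, u20R=u2, D_tot=2)
        net = build_network(p, "histone_only")
        space = StateSpace(net)
        Q = build_generator(net, space).toarray()

        def rate(frm, to):
            nD, nA, n2 = frm
            total = 0.0
            if to == (nD - 1, nA + 1, n2):      # D -> DA
                total = (uA + 1.0 * nA / 2) * nD
            elif to == (nD - 1, nA, n2 + 1):    # D -> D2R
                total = (u2 + al * n2 / 2) * nD
            elif to == (nD + 1, nA - 1, n2):    # DA -> D
                total = (eps + epsp * n2 / 2) * nA
            elif to == (nD + 1, nA, n2 - 1):    # D2R -> D
                total = (1.0 * eps * mu + mu * epsp * nA / 2) * n2
            return total

        idx = {tuple(s[[net.index("D"), net.index("DA"), net.index("D2R")]]): i
               for i, s in enumerate(space.states)}
        for frm, i in idx.items():
            for to, j in idx.items():
                if frm == to:
                    continue
                assert Q[i, j] == pytest.approx(rate(frm, to)), (frm, to)


class TestStationary:
    def test_birth_death_detailed_balance(self):
        """Stationary law of a birth-death generator matches the product
        form computed independently."""
        lam = np.array([1.0, 2.0, 0.5, 0.0])
        gam = np.array([0.0, 0.7, 1.3, 2.1])
        n = 4
        Q = np.zeros((n, n))
        for i in range(n - 1):
            Q[i, i + 1] = lam[i]
            Q[i + 1, i] = gam[i + 1]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        dist = exact_stationary(sp.csr_matrix(Q))
        w = np.ones(n)
        for i in range(1, n):
            w[i] = w[i - 1] * lam[i - 1] / gam[i]
        assert np.allclose(dist.probs, w / w.sum(), atol=1e-12)

    def test_bimodal_extremes_at_small_eps(self, small_params):
        """Slow basal erasure makes the stationary law bimodal: with a
        balancing activating input, both near-extreme macro-states carry
        substantial mass and intermediate states almost none."""
        net = build_network(small_params.replace(eps=0.15, uA=1.5))
        space = StateSpace(net)
        dist = exact_stationary(build_generator(net, space), space)
        iDA = net.index("DA")
        irep = [net.index(s) for s in ("D1R", "D2R", "D12R")]
        act = sum(pr for s, pr in zip(dist.states, dist.probs)
                  if s[iDA] >= 6)
        rep = sum(pr for s, pr in zip(dist.states, dist.probs)
                  if s[irep].sum() >= 6)
        assert act > 0.2 and rep > 0.2
        assert 1.0 - act - rep < 0.1
        assert dist.metadata["residual"] < 1e-10

    def test_peaks_sharpen_as_eps_decreases(self, small_params):
        masses = []
        for eps in (0.5, 0.1, 0.02):
            net = build_network(small_params.replace(eps=eps))
            space = StateSpace(net)
            dist = exact_stationary(build_generator(net, space), space)
            masses.append(dist.probs[space.find(DA=8)]
                          + dist.probs[space.find(D12R=8)])
        assert masses[0] < masses[1] < masses[2]

    def test_smaller_mu_prime_biases_repressed(self, small_params):
        reps = []
        for mup in (1.0, 0.3):
            net = build_network(small_params.replace(eps=0.1, mu_prime=mup))
            space = StateSpace(net)
            dist = exact_stationary(build_generator(net, space), space)
            reps.append(dist.probs[space.find(D12R=8)])
        assert reps[1] > reps[0]

    def test_monotone_input_response(self, small_params):
        """Raising uA raises the active macro-state mass; raising uR raises
        the repressed mass."""
        p = small_params.replace(eps=0.3)

        def masses(pp):
            net = build_network(pp)
            space = StateSpace(net)
            d = exact_stationary(build_generator(net, space), space)
            iDA = net.index("DA")
            irep = [net.index(s) for s in ("D1R", "D2R", "D12R")]
            act = sum(pr for s, pr in zip(d.states, d.probs) if s[iDA] >= 6)
            repm = sum(pr for s, pr in zip(d.states, d.probs)
                       if s[irep].sum() >= 6)
            return act, repm

        a0, _ = masses(p)
        a1, _ = masses(p.with_inputs(uA=1.0))
        _, r0 = masses(p)
        _, r1 = masses(p.with_inputs(u1R=1.0, u2R=1.0))
        assert a1 > a0 and r1 > r0


class TestMFPT:
    def test_start_in_target_is_zero(self, full_net_small):
        space = StateSpace(full_net_small)
        Q = build_generator(full_net_small, space)
        res = exact_mfpt(Q, [space.find(DA=8)])
        assert res.mfpt[space.find(DA=8)] == 0.0

    def test_two_state_chain(self):
        r = 0.37
        Q = sp.csr_matrix(np.array([[-r, r], [0.0, 0.0]]))
        res = exact_mfpt(Q, [1])
        assert res.mfpt[0] == pytest.approx(1.0 / r)

    def test_unreachable_target_is_infinite(self):
        Q = sp.csr_matrix(np.array([[0.0, 0.0], [1.0, -1.0]]))
        res = exact_mfpt(Q, [1])
        assert np.isinf(res.mfpt[0])

    def test_memory_times_grow_as_eps_shrinks(self, small_params):
        taus = []
        for eps in (0.36, 0.12):
            net = build_network(small_params.replace(eps=eps))
            space = StateSpace(net)
            Q = build_generator(net, space)
            tR = exact_mfpt(Q, [space.find(DA=8)]).mfpt[space.find(D12R=8)]
            tA = exact_mfpt(Q, [space.find(D12R=8)]).mfpt[space.find(DA=8)]
            taus.append((tR, tA))
        assert taus[1][0] > taus[0][0] and taus[1][1] > taus[0][1]

    def test_mu_mu_prime_asymmetry(self, small_params):
        """Smaller mu mu' lengthens repressed-state memory but shortens
        active-state memory."""
        out = []
        for m in (1.0, 0.3):
            net = build_network(small_params.replace(eps=0.05, mu=m,
                                                     mu_prime=m))
            space = StateSpace(net)
            Q = build_generator(net, space)
            out.append((exact_mfpt(Q, [space.find(DA=8)])
                        .mfpt[space.find(D12R=8)],
                        exact_mfpt(Q, [space.find(D12R=8)])
                        .mfpt[space.find(DA=8)]))
        assert out[1][0] > out[0][0]
        assert out[1][1] < out[0][1]


class TestReducedChain:
    def test_boundary_rates_vanish(self, small_params):
        net = build_network(small_params.replace(eps=0.05, eps_prime=0.1))
        chain = reduce_to_1d(net)
        assert chain.lam[-1] == 0.0 and chain.gam[0] == 0.0
        assert np.all(chain.lam >= 0) and np.all(chain.gam >= 0)

    def test_matches_full_chain_marginal(self, small_params):
        """Averaged-chain stationary law vs the exact marginal over n12R:
        total variation below 0.1 deep in the slow-erasure regime."""
        p = small_params.replace(eps=1e-3, eps_prime=0.05)
        net = build_network(p)
        chain = reduce_to_1d(net)
        space = StateSpace(net)
        dist = exact_stationary(build_generator(net, space), space)
        marg = np.zeros(9)
        x_idx = net.index("D12R")
        for s, pr in zip(dist.states, dist.probs):
            marg[s[x_idx]] += pr
        tv = 0.5 * np.abs(chain.stationary() - marg).sum()
        assert tv < 0.1

    def test_mass_concentrates_on_extremes(self, small_params):
        chain = reduce_to_1d(build_network(
            small_params.replace(eps=1e-3, eps_prime=0.05)))
        pi = chain.stationary()
        assert pi[1:-1].sum() < 0.05

    def test_warns_outside_regime(self, small_params):
        with pytest.warns(UserWarning):
            reduce_to_1d(build_network(small_params.replace(eps=1.0)))

    def test_birth_death_mfpt_recursions(self):
        """Closed-form MFPT of a 2-level chain against the analytic value."""
        chain = ReducedChain(np.arange(3), np.array([2.0, 1.0, 0.0]),
                             np.array([0.0, 3.0, 1.0]))
        # from x=2 to 0: t2 = 1/g2, t1 = (1 + l1*t2)/g1; total = t1 + t2
        t2 = 1.0
        t1 = (1 + 1.0 * t2) / 3.0
        assert chain.mfpt_to_zero() == pytest.approx(t1 + t2)
        # from 0 to 2: s0 = 1/l0, s1 = (1 + g1*s0)/l1
        s0 = 0.5
        s1 = (1 + 3.0 * s0) / 1.0
        assert chain.mfpt_to_top() == pytest.approx(s0 + s1)


class TestLimitFormulas:
    def test_eps_to_zero_gives_full_repression(self, small_params):
        ls = limit_stationary(small_params.replace(eps=1e-6))
        assert ls.pi_repressed == pytest.approx(1.0, abs=1e-4)

    def test_mu_mu_prime_to_zero_gives_full_repression(self, small_params):
        ls = limit_stationary(small_params.replace(eps=0.01, mu=1e-3,
                                                   mu_prime=1e-3))
        assert ls.pi_repressed == pytest.approx(1.0, abs=1e-4)

    def test_input_monotonicity_of_P(self, small_params):
        p = small_params.replace(eps=0.01, eps_prime=0.1)
        base = limit_stationary(p).log_P
        assert limit_stationary(p.with_inputs(uA=1.0)).log_P < base
        assert limit_stationary(p.with_inputs(u1R=1.0, u2R=1.0)).log_P > base

    def test_autoregulation_decreases_P(self, small_params):
        p = small_params.replace(eps=0.05)
        logs = [limit_stationary(p, p_x=px).log_P for px in (0.0, 1.0, 5.0)]
        assert logs[0] > logs[1] > logs[2]

    def test_limit_agrees_with_reduced_chain_extremes(self, small_params):
        """The exact reduced chain reproduces the piecewise limit law as
        eps -> 0 (difference below 0.01 at eps = 1e-6)."""
        p = small_params.replace(eps=1e-6, eps_prime=0.05)
        chain = reduce_to_1d(build_network(p))
        pi = chain.stationary()
        ls = limit_stationary(p)
        assert abs(pi[-1] - ls.pi_repressed) < 0.01
        assert abs(pi[0] - ls.pi_active) < 0.01

    def test_scaling_structure_of_memory_times(self, small_params):
        p = small_params.replace(eps=0.01)
        assert limit_mfpt_repressed(p) == pytest.approx(
            limit_mfpt_repressed(p.replace(eps=0.02)) * 4.0)
        assert limit_mfpt_active(p) == pytest.approx(
            limit_mfpt_active(p.replace(eps=0.02)) * 2.0)
        # autoregulation lengthens active memory
        t0 = limit_mfpt_active_autoregulated(p, 0.0)
        t1 = limit_mfpt_active_autoregulated(p, 2.0)
        assert t1 > t0


def test_composition_enumeration_count():
    from math import comb
    assert len(list(_compositions(8, 5))) == comb(12, 4)
    assert all(sum(c) == 8 for c in _compositions(8, 5))
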