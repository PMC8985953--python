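"""Exact finite-state Markov analysis of chromatin circuits.

For modest nucleosome counts the chromatin CTMC is small enough (the full
circuit has C(D_tot+4, 4) states) for exact computation of the stationary
distribution and of mean first-passage times (MFPT, the "time to memory
loss").  This module is the brute-force oracle against which the SSA engine
is validated, and also hosts two reduced descriptions valid under time-scale
separation (basal and recruited erasure slow relative to catalysis,
``eps, eps_prime << 1``):

* a one-dimensional birth-death chain in the doubly-repressed coordinate
  ``x = n12R``, obtained by numeric stochastic averaging of the
  ``x``-preserving (fast) subnetwork, and
* closed-form small-``eps`` limits of the stationary law and the memory-loss
  times, with the order-one coefficient functions supplied as pluggable
  callables (default 1), so that limits and monotonicity can be evaluated
  without their exact algebra.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import breadth_first_order, connected_components
from scipy.sparse.linalg import spsolve

from .model import DimensionlessParams, ReactionNetwork, build_network
from .results import FirstPassageResult, StationaryDistribution

__all__ = [
    "StateSpace",
    "build_generator",
    "exact_stationary",
    "exact_mfpt",
    "ReducedChain",
    "reduce_to_1d",
    "LimitStationary",
    "limit_stationary",
    "limit_mfpt_repressed",
    "limit_mfpt_active",
    "limit_mfpt_active_autoregulated",
    "mfpt_scaling_check",
]


# ---------------------------------------------------------------------------
# state space and generator
# ---------------------------------------------------------------------------


def _compositions(total: int, k: int):
    """All k-part compositions of ``total`` (lexicographic)."""
    if k == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, k - 1):
            yield (first,) + rest


class StateSpace:
    """Enumerated product of the conserved-group simplices of a network.

    Only networks whose species are all covered by conserved groups (i.e.
    chromatin-only networks, including protein-QSS compositions) admit a
    finite state space.
    """

    def __init__(self, network: ReactionNetwork):
        covered = {s for g in network.conserved_groups for s in g}
        missing = set(network.species) - covered
        if missing:
            raise ValueError(
                f"species {sorted(missing)} are unbounded; exact analysis "
                "requires a chromatin-only network (use the protein-QSS "
                "composition for coupled circuits)")
        self.network = network
        per_group = [list(_compositions(network.D_tot, len(g)))
                     for g in network.conserved_groups]
        group_idx = [[network.index(s) for s in g]
                     for g in network.conserved_groups]
        states = []
        for combo in product(*per_group):
            vec = np.zeros(network.n_species, dtype=np.int64)
            for idx, counts in zip(group_idx, combo):
                vec[idx] = counts
            states.append(vec)
        self.states = np.array(states, dtype=np.int64)
        self._index = {tuple(s): i for i, s in enumerate(self.states)}

    def __len__(self) -> int:
        return len(self.states)

    def index(self, state) -> int:
        vec = self.network.state_array(state)
        return self._index[tuple(int(v) for v in vec)]

    def find(self, **counts: int) -> int:
        """Index of the unique state matching the given species counts and
        zeros elsewhere (remaining mass on each group's first species)."""
        vec = np.zeros(self.network.n_species, dtype=np.int64)
        for sp, v in counts.items():
            vec[self.network.index(sp)] = v
        for g in self.network.conserved_groups:
            idx = [self.network.index(s) for s in g]
            if g[0] not in counts:
                vec[idx[0]] = self.network.D_tot - vec[idx[1:]].sum()
        return self._index[tuple(int(v) for v in vec)]


def build_generator(network: ReactionNetwork,
                    space: StateSpace | None = None) -> sp.csr_matrix:
    """Sparse CTMC generator Q: Q[s, s'] = total propensity s -> s'.

    Rows sum to zero; off-diagonals are non-negative.
    """
    if space is None:
        space = StateSpace(network)
    if space.network is not network and space.network.species != network.species:
        raise ValueError("state space does not match network")
    _, _, S, _, _, _ = network.arrays()
    rows, cols, vals = [], [], []
    for i, state in enumerate(space.states):
        a = network.propensities(state)
        for r in np.nonzero(a > 0)[0]:
            j = space._index[tuple(int(v) for v in (state + S[r]))]
            rows.append(i)
            cols.append(j)
            vals.append(a[r])
    n = len(space)
    Q = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    Q = Q - sp.diags(np.asarray(Q.sum(axis=1)).ravel())
    return Q.tocsr()


# ---------------------------------------------------------------------------
# stationary distribution and MFPT
# ---------------------------------------------------------------------------


def _closed_classes(Q: sp.csr_matrix) -> list[np.ndarray]:
    """Indices of recurrent (closed) communicating classes."""
    adj = (Q > 0).astype(np.int8)
    n_comp, labels = connected_components(adj, directed=True, connection="strong")
    closed = []
    for c in range(n_comp):
        members = np.nonzero(labels == c)[0]
        sub = adj[members].tocsc()
        outside = np.setdiff1d(np.arange(Q.shape[0]), members)
        if sub[:, outside].nnz == 0:
            closed.append(members)
    return closed


def _stationary_on(Q: sp.csr_matrix, members: np.ndarray) -> np.ndarray:
    Qs = Q[np.ix_(members, members)].toarray()
    n = len(members)
    A = np.vstack([Qs.T, np.ones((1, n))])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def exact_stationary(Q: sp.csr_matrix, space: StateSpace | None = None,
                     metadata: dict | None = None) -> StationaryDistribution:
    """Exact stationary distribution of the CTMC generator ``Q``.

    For an irreducible chain this solves pi Q = 0, sum pi = 1 directly; a
    reducible chain triggers a warning and returns the uniform mixture of
    the per-closed-class stationary laws.  The residual ``||pi Q||_inf`` is
    checked against 1e-10.
    """
    n = Q.shape[0]
    closed = _closed_classes(Q)
    pi = np.zeros(n)
    if len(closed) == 1 and len(closed[0]) == n:
        pi = _stationary_on(Q, np.arange(n))
    else:
        if len(closed) != 1:
            warnings.warn(f"reducible chain: {len(closed)} closed classes; "
                          "returning their uniform mixture", stacklevel=2)
        for members in closed:
            pi[members] += _stationary_on(Q, members) / len(closed)
    residual = float(np.max(np.abs(pi @ Q)))
    if residual > 1e-10:
        warnings.warn(f"stationary residual {residual:.2e} above 1e-10",
                      stacklevel=2)
    meta = {"engine": "cme", "residual": residual}
    meta.update(metadata or {})
    if space is not None:
        return StationaryDistribution(space.states, pi, space.network.species,
                                      metadata=meta)
    return StationaryDistribution(np.arange(n)[:, None], pi,
                                  ("state",), metadata=meta)


def exact_mfpt(Q: sp.csr_matrix, target: Sequence[int]) -> FirstPassageResult:
    """Expected hitting time of ``target`` from every state.

    Solves ``Q_restricted h = -1`` with ``h = 0`` on the target set; states
    from which the target is unreachable get ``inf``.
    """
    n = Q.shape[0]
    target = np.asarray(list(target), dtype=int)
    if target.size == 0:
        raise ValueError("target set must be non-empty")
    mask = np.zeros(n, dtype=bool)
    mask[target] = True
    # states that can reach the target: BFS on the reversed transition graph
    adjT = (Q > 0).astype(np.int8).T.tocsr()
    reach = np.zeros(n, dtype=bool)
    for t in target:
        order = breadth_first_order(adjT, t, return_predecessors=False)
        reach[order] = True
    h = np.full(n, np.inf)
    h[mask] = 0.0
    solve_idx = np.nonzero(reach & ~mask)[0]
    if solve_idx.size:
        Qs = Q[np.ix_(solve_idx, solve_idx)].tocsc()
        rhs = -np.ones(len(solve_idx))
        sol = spsolve(Qs, rhs)
        h[solve_idx] = sol
    if np.any(h[np.isfinite(h)] < -1e-9):
        warnings.warn("negative hitting time from linear solve; "
                      "check generator conditioning", stacklevel=2)
    return FirstPassageResult(h, mask)


# ---------------------------------------------------------------------------
# one-dimensional reduction (stochastic averaging over x = n12R)
# ---------------------------------------------------------------------------


@dataclass
class ReducedChain:
    """Birth-death chain in x = n12R with averaged up/down rates."""

    x: np.ndarray
    lam: np.ndarray      # up-rates, lam[D_tot] = 0
    gam: np.ndarray      # down-rates, gam[0] = 0
    provenance: str = "numeric-averaging"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.lam[-1] != 0.0 or self.gam[0] != 0.0:
            raise ValueError("boundary rates must vanish")
        if np.any(self.lam < 0) or np.any(self.gam < 0):
            raise ValueError("rates must be non-negative")

    @property
    def D_tot(self) -> int:
        return len(self.x) - 1

    def stationary(self) -> np.ndarray:
        """Product-form stationary law (log-space)."""
        D = self.D_tot
        logw = np.full(D + 1, -np.inf)
        logw[0] = 0.0
        acc = 0.0
        for i in range(1, D + 1):
            if self.lam[i - 1] <= 0 or self.gam[i] <= 0:
                if self.lam[i - 1] <= 0:
                    break  # upper states unreachable from below
                acc = np.inf  # gam == 0: mass collapses upward
            else:
                acc += math.log(self.lam[i - 1]) - math.log(self.gam[i])
            logw[i] = acc
        m = np.max(logw[np.isfinite(logw)]) if np.any(np.isfinite(logw)) else 0.0
        w = np.exp(np.clip(logw - m, -745, 709))
        w[~np.isfinite(w)] = 0.0
        if np.any(np.isinf(logw) & (logw > 0)):
            w = np.where(np.isinf(logw) & (logw > 0), 1.0, 0.0)
        return w / w.sum()

    def mfpt_to_zero(self, start: int | None = None) -> float:
        """Expected time to reach x = 0 (the active side) from ``start``
        (default D_tot): the memory-loss time of the repressed state."""
        D = self.D_tot
        if start is None:
            start = D
        t = np.zeros(D + 1)  # t[i] = E[time i -> i-1]
        for i in range(D, 0, -1):
            if self.gam[i] <= 0:
                t[i] = np.inf
            else:
                nxt = t[i + 1] if i < D else 0.0
                t[i] = (1.0 + self.lam[i] * nxt) / self.gam[i]
        return float(np.sum(t[1:start + 1]))

    def mfpt_to_top(self, start: int = 0) -> float:
        """Expected time to reach x = D_tot from ``start`` (default 0): the
        memory-loss time of the active state."""
        D = self.D_tot
        s = np.zeros(D)  # s[i] = E[time i -> i+1]
        for i in range(D):
            if self.lam[i] <= 0:
                s[i] = np.inf
            else:
                prev = s[i - 1] if i > 0 else 0.0
                s[i] = (1.0 + self.gam[i] * prev) / self.lam[i]
        return float(np.sum(s[start:]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.x, "lam": self.lam, "gam": self.gam})


def reduce_to_1d(network: ReactionNetwork,
                 warn_regime: bool = True) -> ReducedChain:
    """Stochastic-averaging reduction of a 5-species chromatin network.

    For each level ``x = n12R`` the x-preserving (fast) subnetwork's exact
    conditional stationary distribution is computed and the x-changing
    propensities are averaged against it, yielding a birth-death chain.
    Valid when erasure is slow relative to catalysis (``eps, eps_prime``
    small); a warning is issued outside that regime.
    """
    if "D12R" not in network.species or len(network.conserved_groups) != 1:
        raise ValueError("reduction requires a single-gene network with D12R")
    p = network.params
    if warn_regime and p is not None and (p.eps > 0.5 or p.eps_prime > 0.5):
        warnings.warn("eps or eps_prime above 0.5: the averaged chain may be "
                      "a poor approximation", stacklevel=2)
    D = network.D_tot
    x_idx = network.index("D12R")
    sub_idx, coeff, S, cat, hill_K, hill_h = network.arrays()
    dx = S[:, x_idx]
    fast = np.nonzero(dx == 0)[0]
    up = np.nonzero(dx == +1)[0]
    down = np.nonzero(dx == -1)[0]
    other = [s for s in network.species if s != "D12R"]
    other_idx = [network.index(s) for s in other]

    lam = np.zeros(D + 1)
    gam = np.zeros(D + 1)
    for x in range(D + 1):
        level_states = []
        for comp in _compositions(D - x, len(other)):
            vec = np.zeros(network.n_species, dtype=np.int64)
            vec[other_idx] = comp
            vec[x_idx] = x
            level_states.append(vec)
        level_states = np.array(level_states)
        index = {tuple(s[o] for o in other_idx): i
                 for i, s in enumerate(level_states)}
        n = len(level_states)
        Qf = np.zeros((n, n))
        a_up = np.zeros(n)
        a_down = np.zeros(n)
        for i, state in enumerate(level_states):
            a = network.propensities(state)
            for r in fast:
                if a[r] > 0:
                    tgt = state + S[r]
                    j = index[tuple(tgt[o] for o in other_idx)]
                    Qf[i, j] += a[r]
            a_up[i] = a[up].sum()
            a_down[i] = a[down].sum()
        np.fill_diagonal(Qf, Qf.diagonal() - Qf.sum(axis=1))
        pi = _stationary_on(sp.csr_matrix(Qf), np.arange(n)) if n > 1 else np.ones(1)
        lam[x] = float(pi @ a_up)
        gam[x] = float(pi @ a_down)
    lam[D] = 0.0
    gam[0] = 0.0
    return ReducedChain(np.arange(D + 1), lam, gam,
                        metadata={"variant": network.variant, "D_tot": D})


# ---------------------------------------------------------------------------
# closed-form small-eps limits
# ---------------------------------------------------------------------------


@dataclass
class LimitStationary:
    """Small-eps stationary law: all mass on x = 0 and x = D_tot."""

    log_P: float
    pi_active: float     # pi(0)
    pi_repressed: float  # pi(D_tot)

    @property
    def P(self) -> float:
        return math.exp(self.log_P) if self.log_P < 700 else math.inf


def _ones(_: int) -> float:
    return 1.0


def limit_stationary(params: DimensionlessParams,
                     K: Callable[[int], float] = _ones,
                     p_x: float | None = None,
                     u_tilde_A: float = 1.0) -> LimitStationary:
    """Closed-form stationary masses in the ``eps << 1`` limit.

    Computes ``P = P1 * P2`` in log space; the stationary law is
    ``pi(0) = 1/(1+P)`` (fully active) and ``pi(D_tot) = P/(1+P)`` (fully
    repressed), zero elsewhere.  ``K`` supplies the order-one per-step
    coefficients (default 1; their exact algebra is not required for the
    limits or monotonicity).  With ``p_x`` set, the positively autoregulated
    variant is evaluated under protein quasi-steady state, where the
    activating drive gains the term ``u_tilde_A * p_x``.
    """
    p = params
    D = p.D_tot
    A = p.alpha + p.alpha_bar + p.alpha_prime
    u12 = p.u_bar_12R
    mm = p.mu * p.mu_prime

    def _log(v: float) -> float:
        return math.log(v) if v > 0 else -math.inf

    if p_x is None:
        log_P1 = _log(p.u_bar_A + u12 + A) - _log(p.u_bar_A + u12 + 1.0)
        uA_closing = p.u_bar_A

        def drive_A(i: int) -> float:
            return p.u_bar_A + (D - i) / D
    else:
        utot = p.u0A + u12
        gain = u_tilde_A * p_x + 1.0
        log_P1 = _log(utot + A) - _log(utot + gain)
        uA_closing = p.u0A

        def drive_A(i: int) -> float:
            return p.u0A + gain * (D - i) / D

    log_P2 = 0.0
    for i in range(1, D):
        num = 2.0 * (u12 + A * i / D)
        den = mm * p.eps_prime * ((D - i) / D) * K(i) * drive_A(i)
        log_P2 += _log(num) - _log(den)
    log_P2 += _log(u12) - _log(mm * p.b * p.beta * p.eps * K(D) * uA_closing)

    log_P = log_P1 + log_P2
    if math.isinf(log_P):
        pi0, piD = (1.0, 0.0) if log_P < 0 else (0.0, 1.0)
    else:
        # pi(Dtot) = P/(1+P) = sigmoid(log P)
        piD = 1.0 / (1.0 + math.exp(-np.clip(log_P, -745, 745)))
        pi0 = 1.0 - piD
    return LimitStationary(log_P, pi0, piD)


def limit_mfpt_repressed(params: DimensionlessParams,
                         K_R: float = 1.0,
                         K_Ri: Callable[[int], float] = _ones,
                         h1: Callable[[float], float] = lambda y: y) -> float:
    """Small-eps memory-loss time of the repressed state,
    ``~ K_R / (mu mu' eps^2) * (1 + sum K_R^i h1(mu mu'))``.

    The default ``h1(y) = y`` satisfies the stated structure (increasing,
    ``h1(0) = 0``); this is a qualitative scaling law, not a fitted value.
    """
    p = params
    mm = p.mu * p.mu_prime
    if mm <= 0 or p.eps <= 0:
        return math.inf
    series = 1.0 + sum(K_Ri(i) * h1(mm) for i in range(1, p.D_tot))
    return K_R / (mm * p.eps ** 2) * series


def limit_mfpt_active(params: DimensionlessParams,
                      K_A: float = 1.0,
                      K_Ai: Callable[[int], float] = _ones,
                      h2: Callable[[float], float] = lambda y: y) -> float:
    """Small-eps memory-loss time of the active state,
    ``~ K_A / eps * (1 + sum h2(mu mu') K_A^i)``."""
    p = params
    if p.eps <= 0:
        return math.inf
    series = 1.0 + sum(h2(p.mu * p.mu_prime) * K_Ai(i)
                       for i in range(1, p.D_tot))
    return K_A / p.eps * series


def limit_mfpt_active_autoregulated(
        params: DimensionlessParams, p_x: float,
        f2: Callable[[float], float] = lambda px: 1.0 + px,
        K_Ai: Callable[[int], float] = _ones,
        h2: Callable[[float, float], float] = lambda px, y: (1.0 + px) * y,
) -> float:
    """Memory-loss time of the active state under positive autoregulation,
    ``~ f2(p_x)/eps * (1 + sum h2(p_x, mu mu') K_A^i)`` with ``f2`` and
    ``h2`` increasing in ``p_x`` and ``h2(p_x, 0) = 0``."""
    p = params
    if p.eps <= 0:
        return math.inf
    series = 1.0 + sum(h2(p_x, p.mu * p.mu_prime) * K_Ai(i)
                       for i in range(1, p.D_tot))
    return f2(p_x) / p.eps * series


# ---------------------------------------------------------------------------
# MFPT scaling in eps
# ---------------------------------------------------------------------------


@dataclass
class MFPTScaling:
    eps_grid: np.ndarray
    tau_repressed: np.ndarray
    tau_active: np.ndarray
    slope_repressed: float
    slope_active: float
    variant: str


def mfpt_scaling_check(params: DimensionlessParams, eps_grid: Sequence[float],
                       variant: str = "full") -> MFPTScaling:
    """Exact-MFPT power laws in ``eps``.

    For each ``eps`` the exact MFPT between the extreme chromatin states is
    computed on the full CME and the log-log slope fitted.  The full circuit
    shows the structural asymmetry (repressed -> active ~ eps^-2,
    active -> repressed ~ eps^-1); the histone-only sub-circuit is symmetric
    (both ~ eps^-1).
    """
    eps_grid = np.asarray(eps_grid, dtype=float)
    taus_R, taus_A = [], []
    for eps in eps_grid:
        net = build_network(params.replace(eps=eps), variant)
        space = StateSpace(net)
        Q = build_generator(net, space)
        if variant == "full":
            repressed = space.find(D12R=net.D_tot)
        else:
            repressed = space.find(D2R=net.D_tot)
        active = space.find(DA=net.D_tot)
        taus_R.append(exact_mfpt(Q, [active]).mfpt[repressed])
        taus_A.append(exact_mfpt(Q, [repressed]).mfpt[active])
    taus_R = np.asarray(taus_R)
    taus_A = np.asarray(taus_A)
    for name, t in (("repressed", taus_R), ("active", taus_A)):
        if np.any(np.diff(t) > 0):  # expect decreasing in eps
            warnings.warn(f"tau_{name} not monotone over the eps grid; "
                          "outside the scaling regime?", stacklevel=2)
    slope_R = float(np.polyfit(np.log(eps_grid), np.log(taus_R), 1)[0])
    slope_A = float(np.polyfit(np.log(eps_grid), np.log(taus_A), 1)[0])
    return MFPTScaling(eps_grid, taus_R, taus_A, slope_R, slope_A, variant)
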