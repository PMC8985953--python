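"""Deterministic (mean-field) analysis of chromatin modification circuits.

The ODE model treats nucleosome counts as continuous fractions
``DA = nA/D_tot`` etc.  It supports steady-state search with stability
classification, one-parameter bifurcation scans with saddle-node
localization, two-parameter stability charts, and quasi-static hysteresis
sweeps of the TF inputs — the deterministic fingerprints of epigenetic
memory (bistability and input-history dependence).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .model import DimensionlessParams, ReactionNetwork, build_network

__all__ = [
    "FractionState",
    "Equilibrium",
    "EquilibriumSet",
    "Trajectory",
    "mean_field_rhs",
    "gene_expression_rhs",
    "simulate_ode",
    "find_equilibria",
    "bifurcation_scan",
    "stability_chart",
    "hysteresis_sweep",
    "relax_to_steady_state",
]


@dataclass
class FractionState:
    """Fractions of nucleosomes in each modified state (D is derived)."""

    DA: float = 0.0
    D1R: float = 0.0
    D2R: float = 0.0
    D12R: float = 0.0
    X: float | None = None
    Z: float | None = None

    def __post_init__(self) -> None:
        for name in ("DA", "D1R", "D2R", "D12R"):
            v = getattr(self, name)
            if not -1e-12 <= v <= 1 + 1e-12:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.D < -1e-9:
            raise ValueError("fractions sum to more than 1")

    @property
    def D(self) -> float:
        return 1.0 - self.DA - self.D1R - self.D2R - self.D12R

    @property
    def DR(self) -> float:
        return self.D1R + self.D2R + self.D12R

    def array(self) -> np.ndarray:
        return np.array([self.DA, self.D1R, self.D2R, self.D12R])


def mean_field_rhs(state: FractionState | np.ndarray,
                   params: DimensionlessParams) -> np.ndarray:
    """Hand-written mean-field RHS of the full circuit.

    Returns d/dtau of (DA, D1R, D2R, D12R); the unmodified fraction D obeys
    dD/dtau = -(sum of these), so total nucleosome fraction is conserved.
    This closed form is asserted (in tests) to agree with the mass-action
    mean field generated from :func:`chromem.model.build_network`.
    """
    if isinstance(state, FractionState):
        DA, D1R, D2R, D12R = state.array()
    else:
        DA, D1R, D2R, D12R = np.asarray(state, dtype=float)
    p = params
    D = 1.0 - DA - D1R - D2R - D12R
    K9 = D2R + D12R
    ME = D1R + D12R
    w2 = p.u_bar_2R + p.alpha * K9 + p.alpha_bar * ME   # H3K9me writing drive
    w1 = p.u_bar_1R + p.alpha_prime * K9                # CpGme writing drive
    dDA = (p.u_bar_A + DA) * D - p.eps * DA - p.eps_prime * (K9 + ME) * DA
    dD1R = (w1 * D - w2 * D1R
            - p.beta * p.eps * p.mu_prime * D1R
            - p.mu_prime * p.eps_prime * DA * D1R
            + p.b * p.eps * p.mu * D12R
            + p.mu * p.eps_prime * DA * D12R)
    dD2R = (w2 * D - w1 * D2R
            - p.b * p.eps * p.mu * D2R
            - p.mu * p.eps_prime * DA * D2R
            + p.beta * p.eps * p.mu_prime * D12R
            + p.mu_prime * p.eps_prime * DA * D12R)
    dD12R = (w1 * D2R + w2 * D1R
             - (p.b * p.eps * p.mu + p.beta * p.eps * p.mu_prime) * D12R
             - (p.mu + p.mu_prime) * p.eps_prime * DA * D12R)
    return np.array([dDA, dD1R, dD2R, dD12R])


def gene_expression_rhs(state: FractionState, params: DimensionlessParams,
                        alpha_x_bar: float | None = None,
                        gamma_x_bar: float | None = None) -> float:
    """dX/dtau = alpha_x_bar * DA - gamma_x_bar * X.

    With ``p_x = alpha_x_bar / gamma_x_bar`` the steady state is
    ``X* = p_x * DA``.  Defaults come from ``params`` (``alpha_x_bar =
    p_x * gamma_x_bar``).
    """
    if gamma_x_bar is None:
        gamma_x_bar = params.gamma_x_bar
    if alpha_x_bar is None:
        alpha_x_bar = params.p_x * gamma_x_bar
    X = state.X if state.X is not None else 0.0
    return alpha_x_bar * state.DA - gamma_x_bar * X


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Sampled ODE trajectory over all network species (fractions)."""

    t: np.ndarray
    states: np.ndarray  # shape (len(t), n_species)
    species: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(self.species))
        df.insert(0, "tau", self.t)
        return df

    def final(self) -> np.ndarray:
        return self.states[-1]

    def conservation_drift(self, groups: Sequence[Sequence[str]]) -> float:
        drift = 0.0
        for group in groups:
            idx = [self.species.index(s) for s in group]
            totals = self.states[:, idx].sum(axis=1)
            drift = max(drift, float(np.abs(totals - totals[0]).max()))
        return drift


def _fraction_init(network: ReactionNetwork, init) -> np.ndarray:
    """Accept a FractionState, mapping of fractions, or array over species."""
    if isinstance(init, FractionState):
        mapping = {"DA": init.DA, "D1R": init.D1R, "D2R": init.D2R,
                   "D12R": init.D12R, "D": init.D}
        if init.X is not None:
            mapping["X"] = init.X
        if init.Z is not None:
            mapping["Z"] = init.Z
        init = mapping
    if isinstance(init, dict):
        x = np.zeros(network.n_species)
        for sp, v in init.items():
            x[network.index(sp)] = v
        # fill each conserved group's first species with the remainder if unset
        for group in network.conserved_groups:
            idx = [network.index(s) for s in group]
            if group[0] not in init:
                x[idx[0]] = 1.0 - x[idx[1:]].sum()
        return x
    x = np.asarray(init, dtype=float)
    if x.shape != (network.n_species,):
        raise ValueError("initial state has wrong length")
    return x


def simulate_ode(network: ReactionNetwork, init, duration: float,
                 t_eval: np.ndarray | None = None, method: str = "LSODA",
                 rtol: float = 1e-9, atol: float = 1e-12) -> Trajectory:
    """Integrate the mean-field ODEs of ``network`` from ``init``.

    ``init`` may be a :class:`FractionState`, a mapping species->fraction, or
    a full fraction vector.  Raises ``RuntimeError`` with solver diagnostics
    on integration failure.
    """
    x0 = _fraction_init(network, init)
    sol = solve_ivp(lambda _, x: network.mean_field(x), (0.0, duration), x0,
                    t_eval=t_eval, method=method, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return Trajectory(sol.t, sol.y.T, network.species)


# ---------------------------------------------------------------------------
# equilibria
# ---------------------------------------------------------------------------


@dataclass
class Equilibrium:
    state: np.ndarray            # full fraction vector over network.species
    stability: str               # "stable" | "unstable" | "marginal"
    leading_eig: float           # max real part of the Jacobian spectrum

    def value(self, network: ReactionNetwork, species: str) -> float:
        return float(self.state[network.index(species)])


@dataclass
class EquilibriumSet:
    equilibria: list[Equilibrium]
    classification: str
    network: ReactionNetwork = field(repr=False)

    @property
    def stable(self) -> list[Equilibrium]:
        return [e for e in self.equilibria if e.stability == "stable"]

    @property
    def unstable(self) -> list[Equilibrium]:
        return [e for e in self.equilibria if e.stability == "unstable"]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, e in enumerate(self.equilibria):
            row = {"id": i, "stability": e.stability, "leading_eig": e.leading_eig}
            row.update({s: e.state[j] for j, s in enumerate(self.network.species)})
            rows.append(row)
        return pd.DataFrame(rows)


def _free_indices(network: ReactionNetwork) -> tuple[list[int], list[tuple[int, list[int]]]]:
    """Free coordinates = all species except each conserved group's first."""
    dep = []
    free = list(range(network.n_species))
    for group in network.conserved_groups:
        d = network.index(group[0])
        rest = [network.index(s) for s in group[1:]]
        dep.append((d, rest))
        free.remove(d)
    return free, dep


def _full_from_free(y: np.ndarray, n_species: int, free: list[int],
                    dep: list[tuple[int, list[int]]]) -> np.ndarray:
    x = np.zeros(n_species)
    x[free] = y
    for d, rest in dep:
        x[d] = 1.0 - x[rest].sum()
    return x


def _classify(network: ReactionNetwork, stable: list[Equilibrium]) -> str:
    n = len(stable)
    if n == 0:
        return "none"
    if n == 1 and len(network.conserved_groups) == 1:
        e = stable[0]
        DA = e.value(network, "DA") if "DA" in network.species else 0.0
        DR = sum(e.value(network, s) for s in network.species
                 if s in ("D1R", "D2R", "D12R"))
        if DA > 0.5:
            return "monostable_active"
        if DR > 0.5:
            return "monostable_repressed"
        return "monostable_other"
    return {1: "monostable_other", 2: "bistable", 3: "tristable",
            4: "quadristable"}.get(n, f"{n}_stable")


def find_equilibria(network: ReactionNetwork, n_starts: int = 200,
                    seed: int = 0, tol: float = 1e-10, merge_tol: float = 1e-6,
                    tol_eig: float = 1e-8,
                    pre_relax: float = 25.0) -> EquilibriumSet:
    """Multistart root search for steady states, with Jacobian stability.

    Starts are Dirichlet(1,...,1) samples over each conserved simplex plus
    the simplex vertices; protein coordinates start at their quasi-steady
    value.  Half of the starts are first relaxed along the flow for
    ``pre_relax`` time units so that every attractor basin feeds the Newton
    polish (unstable equilibria are still reached from the raw starts).
    Equilibria closer than ``merge_tol`` (sup-norm) are merged; states
    outside the simplex (beyond 1e-9) are discarded.
    """
    rng = np.random.default_rng(seed)
    free, dep = _free_indices(network)
    ns = network.n_species
    protein_idx = [i for i, s in enumerate(network.species) if s in ("X", "Z")]

    def rhs_free(y: np.ndarray) -> np.ndarray:
        x = _full_from_free(y, ns, free, dep)
        return network.mean_field(x)[free]

    starts = []
    for group in network.conserved_groups:
        k = len(group)
        idx = [network.index(s) for s in group]
        samples = rng.dirichlet(np.ones(k), size=n_starts)
        verts = np.eye(k)
        starts.append((idx, np.vstack([samples, verts])))
    n_total = max(s.shape[0] for _, s in starts)

    found: list[np.ndarray] = []
    for i in range(n_total):
        x0 = np.zeros(ns)
        for idx, samples in starts:
            x0[np.asarray(idx)] = samples[i % samples.shape[0]]
        p = network.params
        if protein_idx and p is not None and "DA" in network.species:
            x0[protein_idx] = p.p_x * x0[network.index("DA")]
        if pre_relax > 0 and i % 2 == 0:
            relax = solve_ivp(lambda _, x: network.mean_field(x),
                              (0.0, pre_relax), x0, method="RK45",
                              rtol=1e-6, atol=1e-9)
            if relax.success:
                x0 = relax.y[:, -1]
        sol = root(rhs_free, x0[free], method="hybr", tol=1e-12)
        if not sol.success:
            continue
        x = _full_from_free(sol.x, ns, free, dep)
        if np.any(x < -1e-9) or np.any(x[: ns if not protein_idx else min(protein_idx)] > 1 + 1e-9):
            continue
        if np.max(np.abs(network.mean_field(x))) > tol:
            continue
        if not any(np.max(np.abs(x - f)) < merge_tol for f in found):
            found.append(x)

    equilibria = []
    for x in found:
        J = _jacobian_free(network, x, free, dep)
        lead = float(np.max(np.linalg.eigvals(J).real))
        if lead < -tol_eig:
            stability = "stable"
        elif lead > tol_eig:
            stability = "unstable"
        else:
            stability = "marginal"
        equilibria.append(Equilibrium(np.clip(x, 0.0, None), stability, lead))
    equilibria.sort(key=lambda e: -e.state[network.index("DA")]
                    if "DA" in network.species else 0.0)
    if not equilibria:
        warnings.warn("no equilibrium converged from any start", stacklevel=2)
    stable = [e for e in equilibria if e.stability == "stable"]
    return EquilibriumSet(equilibria, _classify(network, stable), network)


def _jacobian_free(network: ReactionNetwork, x: np.ndarray,
                   free: list[int], dep: list[tuple[int, list[int]]],
                   h: float = 1e-7) -> np.ndarray:
    y0 = x[free]
    f0 = network.mean_field(x)[free]
    n = len(free)
    J = np.zeros((n, n))
    for j in range(n):
        y = y0.copy()
        y[j] += h
        xj = _full_from_free(y, network.n_species, free, dep)
        J[:, j] = (network.mean_field(xj)[free] - f0) / h
    return J


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------


@dataclass
class BifurcationScan:
    param: str
    grid: np.ndarray
    sets: list[EquilibriumSet]
    saddle_nodes: list[float]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v, eqset in zip(self.grid, self.sets):
            for i, e in enumerate(eqset.equilibria):
                row = {"value": v, "equilibrium": i, "stability": e.stability}
                row.update({s: e.state[j]
                            for j, s in enumerate(eqset.network.species)})
                rows.append(row)
        return pd.DataFrame(rows)

    def n_stable(self) -> np.ndarray:
        return np.array([len(s.stable) for s in self.sets])


def _network_factory(params: DimensionlessParams, scan_param: str,
                     variant: str) -> Callable[[float], ReactionNetwork]:
    valid = {"eps", "mu", "mu_prime", "eps_prime", "alpha", "uA", "u1R", "u2R"}
    if scan_param not in valid:
        raise ValueError(f"scan parameter must be one of {sorted(valid)}")

    def factory(value: float) -> ReactionNetwork:
        return build_network(params.replace(**{scan_param: value}), variant)

    return factory


def bifurcation_scan(params: DimensionlessParams | None, scan_param: str,
                     grid: Sequence[float], variant: str = "full",
                     factory: Callable[[float], ReactionNetwork] | None = None,
                     n_starts: int = 60, seed: int = 0,
                     refine_tol: float = 1e-3) -> BifurcationScan:
    """Equilibria along a monotone parameter grid with saddle-node bisection.

    ``factory`` overrides the default parameter-replacement network builder
    (used e.g. to scan ``p_x`` of an autoregulated circuit).  Saddle-node
    points are bisected to relative width ``refine_tol`` between grid points
    where the stable-equilibrium count changes.
    """
    grid = np.asarray(grid, dtype=float)
    if not (np.all(np.diff(grid) > 0) or np.all(np.diff(grid) < 0)):
        raise ValueError("grid must be monotone")
    if factory is None:
        if params is None:
            raise ValueError("either params or factory must be given")
        factory = _network_factory(params, scan_param, variant)

    def solve(v: float) -> EquilibriumSet:
        return find_equilibria(factory(v), n_starts=n_starts, seed=seed)

    sets = [solve(v) for v in grid]
    counts = [len(s.stable) for s in sets]
    saddle_nodes = []
    for i in range(len(grid) - 1):
        if counts[i] != counts[i + 1]:
            lo, hi = grid[i], grid[i + 1]
            c_lo = counts[i]
            while abs(hi - lo) > refine_tol * max(abs(hi), abs(lo), 1e-30):
                mid = 0.5 * (lo + hi)
                if len(solve(mid).stable) == c_lo:
                    lo = mid
                else:
                    hi = mid
            saddle_nodes.append(0.5 * (lo + hi))
    return BifurcationScan(scan_param, grid, sets, saddle_nodes)


def stability_chart(params: DimensionlessParams, x_param: str,
                    x_grid: Sequence[float], y_param: str,
                    y_grid: Sequence[float], variant: str = "full",
                    n_starts: int = 40, seed: int = 0) -> pd.DataFrame:
    """Classification over a 2-parameter grid (long format).

    Columns: ``x_param``, ``y_param``, ``classification``, ``n_stable``.
    Per-cell failures are recorded as classification ``unknown``.
    """
    rows = []
    for yv in y_grid:
        for xv in x_grid:
            p = params.replace(**{x_param: xv, y_param: yv})
            try:
                eqset = find_equilibria(build_network(p, variant),
                                        n_starts=n_starts, seed=seed)
                rows.append({x_param: xv, y_param: yv,
                             "classification": eqset.classification,
                             "n_stable": len(eqset.stable)})
            except Exception:  # pragma: no cover - defensive
                rows.append({x_param: xv, y_param: yv,
                             "classification": "unknown", "n_stable": -1})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# quasi-static sweeps
# ---------------------------------------------------------------------------


def relax_to_steady_state(network: ReactionNetwork, init, tau_relax: float = 1e3,
                          tol: float = 1e-10, max_rounds: int = 4) -> np.ndarray:
    """Integrate until the RHS sup-norm drops below ``tol``, Newton-polishing
    at the end of each round.  Raises ``RuntimeError`` on non-convergence."""
    x = _fraction_init(network, init)
    free, dep = _free_indices(network)
    for _ in range(max_rounds):
        traj = simulate_ode(network, x, tau_relax)
        x = traj.final()
        sol = root(lambda y: network.mean_field(
            _full_from_free(y, network.n_species, free, dep))[free],
            x[free], method="hybr", tol=1e-13)
        if sol.success:
            cand = _full_from_free(sol.x, network.n_species, free, dep)
            # accept the polish only if it stays near the integrated state
            if np.max(np.abs(cand - x)) < 0.1 and np.all(cand > -1e-9):
                x = cand
        if np.max(np.abs(network.mean_field(x))) < tol:
            return np.clip(x, 0.0, None)
        tau_relax *= 10
    raise RuntimeError("steady-state relaxation did not converge")


@dataclass
class IOCharacteristic:
    """Quasi-static input/output sweep (up then down)."""

    input_name: str
    values: np.ndarray
    up: np.ndarray       # (len(values), n_species) steady states, ascending pass
    down: np.ndarray     # same grid, descending pass (stored in grid order)
    species: tuple[str, ...]

    def summary(self) -> pd.DataFrame:
        def block(states, direction):
            df = pd.DataFrame(states, columns=list(self.species))
            df.insert(0, self.input_name, self.values)
            df.insert(1, "direction", direction)
            if {"D1R", "D2R", "D12R"} <= set(self.species):
                df["DR"] = df["D1R"] + df["D2R"] + df["D12R"]
            return df
        return pd.concat([block(self.up, "up"), block(self.down, "down")],
                         ignore_index=True)

    def is_hysteretic(self, species: str = "DA", tol: float = 0.1) -> bool:
        j = self.species.index(species)
        return bool(np.max(np.abs(self.up[:, j] - self.down[:, j])) > tol)


def hysteresis_sweep(params: DimensionlessParams, input_name: str,
                     values: Sequence[float], init,
                     variant: str = "full",
                     factory: Callable[[float], ReactionNetwork] | None = None,
                     tau_relax: float = 1e3, tol: float = 1e-9) -> IOCharacteristic:
    """Quasi-static continuation of steady states along an input ramp.

    ``input_name`` is ``"uA"`` or ``"uR"`` (the latter sets u1R = u2R = uR).
    At each input value the system is integrated to steady state starting
    from the previous converged state; the sweep goes up the grid and then
    back down, exposing hysteresis when the two passes disagree.
    """
    values = np.asarray(values, dtype=float)
    if factory is None:
        if input_name == "uR":
            def factory(v):
                return build_network(params.with_inputs(u1R=v, u2R=v), variant)
        elif input_name in ("uA", "u1R", "u2R"):
            def factory(v):
                return build_network(params.with_inputs(**{input_name: v}), variant)
        else:
            raise ValueError(f"unknown input {input_name!r}")

    net0 = factory(values[0])
    x = _fraction_init(net0, init)
    up = np.zeros((len(values), net0.n_species))
    for i, v in enumerate(values):
        x = relax_to_steady_state(factory(v), x, tau_relax, tol)
        up[i] = x
    down = np.zeros_like(up)
    for i in range(len(values) - 1, -1, -1):
        x = relax_to_steady_state(factory(values[i]), x, tau_relax, tol)
        down[i] = x
    return IOCharacteristic(input_name, values, up, down, net0.species)
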