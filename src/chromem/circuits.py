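"""Gene-expression coupling and regulatory-motif composition.

Two motifs are built on top of the chromatin modification circuit:

* **positive autoregulation** — the gene product X recruits writers of the
  activating mark, so the activating drive becomes ``u0A + uA_tilde * X_bar``
  (linear default, Hill optional);
* **mutual repression** — two positively autoregulated genes whose products
  recruit writers of repressive marks to each other, the chromatin version
  of a toggle switch.

Each motif is available in two equivalent representations: an *explicit*
network with protein species (X, Z) and production/decay reactions, used by
the SSA engine, and a *protein-QSS* chromatin-only network in which the
protein-mediated drives appear as catalysed reactions (autoregulation is
then exactly an increase of the activating auto-catalysis by
``uA_tilde * p_x``), used by the ODE/CME/reduced analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .model import (CHROMATIN_SPECIES, DimensionlessParams, Reaction,
                    ReactionNetwork, build_network)
from .ode import relax_to_steady_state
from .ssa import SSARun, ssa_run

__all__ = [
    "GeneCircuit",
    "PerturbationEvent",
    "make_autoregulated",
    "make_mutual_repression",
    "apply_events_ssa",
    "robustness_scan",
    "with_coefficients",
]


def with_coefficients(network: ReactionNetwork,
                      overrides: dict[str, float]) -> ReactionNetwork:
    """Copy of ``network`` with reaction coefficients replaced by label."""
    labels = {r.label for r in network.reactions}
    unknown = set(overrides) - labels
    if unknown:
        raise ValueError(f"unknown reaction labels: {sorted(unknown)}")
    rxns = [replace(r, coefficient=overrides.get(r.label, r.coefficient))
            for r in network.reactions]
    return ReactionNetwork(network.species, rxns, network.D_tot,
                           network.variant, network.conserved_groups,
                           network.params)


@dataclass
class GeneCircuit:
    """A chromatin circuit coupled to gene expression."""

    network: ReactionNetwork            # explicit proteins (SSA engine)
    qss_network: ReactionNetwork        # protein quasi-steady state (ODE/CME)
    params: DimensionlessParams
    p_x: float
    p_z: float | None = None
    coupling: str = "linear"
    metadata: dict = field(default_factory=dict)


def _hill_params(coupling: str, hill: tuple[float, float] | None,
                 scale: float) -> tuple[float, float] | None:
    """Hill parameters for a catalysed drive whose argument is scaled by
    ``scale`` (the QSS substitution X = p_x * DA rescales the threshold)."""
    if coupling == "linear":
        return None
    if hill is None:
        raise ValueError("hill coupling requires (threshold, coefficient)")
    K, h = hill
    if K <= 0 or h <= 0:
        raise ValueError("hill threshold and coefficient must be > 0")
    if scale <= 0:
        raise ValueError("hill coupling with zero protein gain is degenerate")
    return (K / scale, h)


def make_autoregulated(params: DimensionlessParams, p_x: float,
                       u_tilde_A: float = 1.0, gamma_x_bar: float = 1.0,
                       coupling: str = "linear",
                       hill: tuple[float, float] | None = None,
                       variant: str = "full") -> GeneCircuit:
    """TF-enabled positive autoregulation: X recruits writers of DA.

    The chromatin drive on D -> DA gains the term ``u_tilde_A * X_bar``
    (``X_bar = nX / D_tot``); X is produced at rate ``alpha_x_bar * nA`` with
    ``alpha_x_bar = p_x * gamma_x_bar`` and decays at ``gamma_x_bar``.  With
    ``p_x = 0`` the circuit is the open-loop chromatin circuit plus an inert
    protein.  Under protein QSS the coupling is exactly equivalent to
    raising the activating auto-catalysis coefficient from 1 to
    ``1 + u_tilde_A * p_x`` (linear coupling).
    """
    if coupling not in ("linear", "hill"):
        raise ValueError("coupling must be 'linear' or 'hill'")
    if p_x < 0 or u_tilde_A < 0 or gamma_x_bar <= 0:
        raise ValueError("p_x, u_tilde_A must be >= 0 and gamma_x_bar > 0")
    base = build_network(params, variant)
    species = tuple(base.species) + ("X",)
    rxns = list(base.reactions)
    rxns.append(Reaction("A<-X", "D", (("D", -1), ("DA", +1)), ("X",),
                         u_tilde_A, hill=_hill_params(coupling, hill, 1.0)))
    rxns.append(Reaction("P1", "DA", (("X", +1),), (), p_x * gamma_x_bar))
    rxns.append(Reaction("P2", "X", (("X", -1),), (), gamma_x_bar))
    explicit = ReactionNetwork(species, rxns, params.D_tot,
                               f"autoregulated_{variant}",
                               conserved_groups=[base.species],
                               params=params.replace(p_x=p_x,
                                                     gamma_x_bar=gamma_x_bar))
    qss_rxns = list(base.reactions)
    if p_x > 0:
        qss_rxns.append(Reaction(
            "A<-X(qss)", "D", (("D", -1), ("DA", +1)), ("DA",),
            u_tilde_A * (p_x if coupling == "linear" else 1.0),
            hill=_hill_params(coupling, hill, p_x)))
    qss = ReactionNetwork(base.species, qss_rxns, params.D_tot,
                          f"autoregulated_{variant}_qss",
                          conserved_groups=[base.species],
                          params=params.replace(p_x=p_x,
                                                gamma_x_bar=gamma_x_bar))
    return GeneCircuit(explicit, qss, params, p_x, coupling=coupling,
                       metadata={"u_tilde_A": u_tilde_A,
                                 "gamma_x_bar": gamma_x_bar})


def _suffixed(base: ReactionNetwork, suffix: str) -> list[Reaction]:
    out = []
    for r in base.reactions:
        out.append(Reaction(
            label=f"{r.label}{suffix}",
            substrate=f"{r.substrate}{suffix}",
            stoich=tuple((f"{sp}{suffix}", d) for sp, d in r.stoich),
            catalysts=tuple(f"{c}{suffix}" for c in r.catalysts),
            coefficient=r.coefficient, hill=r.hill))
    return out


def make_mutual_repression(params_x: DimensionlessParams,
                           params_z: DimensionlessParams | None = None,
                           p_x: float = 1.0, p_z: float | None = None,
                           u_tilde_A: float = 1.0,
                           u_tilde_1R: float = 1.0,
                           u_tilde_2R: float | None = None,
                           gamma_bar: float = 1.0,
                           variant: str = "full") -> GeneCircuit:
    """Two mutually repressing, positively autoregulated genes.

    Gene X's product recruits writers of repressive modifications to gene Z
    and vice versa: gene X's CpGme/H3K9me drives gain
    ``u_tilde_iR * Z_bar``, while each gene keeps its own positive
    autoregulation ``u_tilde_A * self``.  Both repressive drives are coupled
    equally by default (``u_tilde_2R = u_tilde_1R``).  Species are suffixed
    ``:X`` / ``:Z``; with ``p_x = p_z = 0`` the genes decouple into two
    open-loop circuits.
    """
    if params_z is None:
        params_z = params_x
    if params_z.D_tot != params_x.D_tot:
        raise ValueError("both genes must share D_tot")
    if p_z is None:
        p_z = p_x
    if u_tilde_2R is None:
        u_tilde_2R = u_tilde_1R
    genes = (("·X", ":X", params_x, p_x, "X"), ("·Z", ":Z", params_z, p_z, "Z"))
    species: list[str] = []
    groups: list[tuple[str, ...]] = []
    rxns: list[Reaction] = []
    qss_rxns: list[Reaction] = []
    for _, suf, prm, p_self, prot in genes:
        base = build_network(prm, variant)
        gene_species = tuple(f"{s}{suf}" for s in base.species)
        species.extend(gene_species)
        groups.append(gene_species)
        rxns.extend(_suffixed(base, suf))
        qss_rxns.extend(_suffixed(base, suf))
        # positive autoregulation (explicit and QSS forms)
        rxns.append(Reaction(f"A<-{prot}", f"D{suf}",
                             ((f"D{suf}", -1), (f"DA{suf}", +1)),
                             (prot,), u_tilde_A))
        if p_self > 0:
            qss_rxns.append(Reaction(f"A<-{prot}(qss)", f"D{suf}",
                                     ((f"D{suf}", -1), (f"DA{suf}", +1)),
                                     (f"DA{suf}",), u_tilde_A * p_self))
        rxns.append(Reaction(f"P1{suf}", f"DA{suf}", ((prot, +1),), (),
                             p_self * gamma_bar))
        rxns.append(Reaction(f"P2{suf}", prot, ((prot, -1),), (), gamma_bar))

    # cross-repression: the opposing product drives repressive writing
    def _cross(suf: str, other_prot: str, other_DA: str, other_p: float):
        pairs = [("D", "D1R", u_tilde_1R), ("D2R", "D12R", u_tilde_1R),
                 ("D", "D2R", u_tilde_2R), ("D1R", "D12R", u_tilde_2R)]
        for frm, to, u in pairs:
            rxns.append(Reaction(f"{frm}>{to}<-{other_prot}", f"{frm}{suf}",
                                 ((f"{frm}{suf}", -1), (f"{to}{suf}", +1)),
                                 (other_prot,), u))
            if other_p > 0:
                qss_rxns.append(Reaction(
                    f"{frm}>{to}<-{other_prot}(qss)", f"{frm}{suf}",
                    ((f"{frm}{suf}", -1), (f"{to}{suf}", +1)),
                    (other_DA,), u * other_p))

    _cross(":X", "Z", "DA:Z", p_z)
    _cross(":Z", "X", "DA:X", p_x)

    D_tot = params_x.D_tot
    explicit = ReactionNetwork(species + ["X", "Z"], rxns, D_tot,
                               f"mutual_repression_{variant}",
                               conserved_groups=groups, params=params_x)
    qss = ReactionNetwork(species, qss_rxns, D_tot,
                          f"mutual_repression_{variant}_qss",
                          conserved_groups=groups, params=params_x)
    return GeneCircuit(explicit, qss, params_x, p_x, p_z,
                       metadata={"u_tilde_A": u_tilde_A,
                                 "u_tilde_1R": u_tilde_1R,
                                 "u_tilde_2R": u_tilde_2R,
                                 "gamma_bar": gamma_bar})


# ---------------------------------------------------------------------------
# perturbation protocols
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PerturbationEvent:
    """A timed intervention on a running simulation.

    ``action``: ``reset_protein_to_zero`` (target = protein species),
    ``overexpress_protein`` (set the protein count to ``magnitude``), or
    ``set_input`` (replace the coefficient of the reaction labelled
    ``target`` by ``magnitude``).
    """

    time: float
    action: str
    target: str
    magnitude: float = 0.0

    def __post_init__(self) -> None:
        if self.action not in ("reset_protein_to_zero", "overexpress_protein",
                               "set_input"):
            raise ValueError(f"unknown action {self.action!r}")


def apply_events_ssa(network: ReactionNetwork, init, t_max: float, seed: int,
                     events: Sequence[PerturbationEvent],
                     sample_times: np.ndarray | None = None) -> SSARun:
    """Run the SSA with state/parameter interventions at fixed times.

    The simulation is segmented at event times; each segment resumes from
    the (possibly modified) state with fresh propensities.  Events beyond
    ``t_max`` are rejected.
    """
    events = sorted(events, key=lambda e: e.time)
    if events and (events[0].time < 0 or events[-1].time > t_max):
        raise ValueError("event times must lie within [0, t_max]")
    seeds = iter(np.random.SeedSequence(seed).generate_state(len(events) + 1) >> 1)
    n = network.state_array(init).copy()
    net = network
    t = 0.0
    all_t, all_s = [], []
    applied = []
    for ev in list(events) + [None]:
        t_seg = t_max if ev is None else ev.time
        st = None
        if sample_times is not None:
            upper = (sample_times < t_seg) if ev else (sample_times <= t_seg)
            keep = (sample_times >= t) & upper
            st = sample_times[keep]
        run = ssa_run(net, n, t_seg, next(seeds), sample_times=st, t0=t,
                      validate=False)
        n = run.state_end
        t = run.t_end
        if st is not None and len(run.samples):
            all_t.append(run.sample_times)
            all_s.append(run.samples)
        if ev is None:
            break
        if ev.action == "reset_protein_to_zero":
            if ev.target in net.species:
                n[net.index(ev.target)] = 0
            else:
                raise ValueError(f"event targets missing species {ev.target!r}")
        elif ev.action == "overexpress_protein":
            if ev.target not in net.species:
                raise ValueError(f"event targets missing species {ev.target!r}")
            n[net.index(ev.target)] = int(ev.magnitude)
        elif ev.action == "set_input":
            net = with_coefficients(net, {ev.target: ev.magnitude})
        applied.append(ev)
        t = t_seg
    samples = np.vstack(all_s) if all_s else None
    times = np.concatenate(all_t) if all_t else None
    return SSARun(seed=seed, t_end=t, status="tmax", state_end=n,
                  species=net.species, sample_times=times, samples=samples)


def apply_events_ode(network: ReactionNetwork, init, t_max: float,
                     events: Sequence[PerturbationEvent],
                     n_samples: int = 200):
    """Deterministic counterpart of :func:`apply_events_ssa`.

    Integration restarts from the modified state at each event time;
    protein magnitudes are interpreted as fractions of ``D_tot``.  Returns
    a :class:`~chromem.ode.Trajectory` over the full horizon.
    """
    from .ode import Trajectory, _fraction_init, simulate_ode

    events = sorted(events, key=lambda e: e.time)
    if events and (events[0].time < 0 or events[-1].time > t_max):
        raise ValueError("event times must lie within [0, t_max]")
    x = _fraction_init(network, init)
    net = network
    t = 0.0
    ts, xs = [], []
    for ev in list(events) + [None]:
        t_seg = t_max if ev is None else ev.time
        if t_seg > t:
            n_pts = max(2, int(np.ceil(n_samples * (t_seg - t) / t_max)))
            seg = simulate_ode(net, x, t_seg - t,
                               t_eval=np.linspace(0.0, t_seg - t, n_pts))
            ts.append(seg.t + t)
            xs.append(seg.states)
            x = seg.final().copy()
        if ev is None:
            break
        if ev.action == "reset_protein_to_zero":
            if ev.target not in net.species:
                raise ValueError(f"event targets missing species {ev.target!r}")
            x[net.index(ev.target)] = 0.0
        elif ev.action == "overexpress_protein":
            if ev.target not in net.species:
                raise ValueError(f"event targets missing species {ev.target!r}")
            x[net.index(ev.target)] = float(ev.magnitude)
        elif ev.action == "set_input":
            net = with_coefficients(net, {ev.target: ev.magnitude})
        t = t_seg
    return Trajectory(np.concatenate(ts), np.vstack(xs), net.species)


# ---------------------------------------------------------------------------
# robustness of the active state to repressive inputs
# ---------------------------------------------------------------------------


def robustness_scan(params: DimensionlessParams, uR_grid: Sequence[float],
                    p_x_grid: Sequence[float], u_tilde_A: float = 1.0,
                    variant: str = "full", threshold: float = 0.5):
    """Persistence of the active state against a repressive drive.

    For each autoregulation strength ``p_x`` the QSS circuit is continued
    from the active state along increasing ``uR`` (= u1R = u2R); the scan
    records the steady-state DA and the critical input ``uR*`` at which the
    active branch collapses (first DA < ``threshold``; inf if it never
    does).  Returns ``(DataFrame, {p_x: uR*})``.
    """
    import pandas as pd

    uR_grid = np.asarray(uR_grid, dtype=float)
    rows, crit = [], {}
    for p_x in p_x_grid:
        x = None
        crit[p_x] = np.inf
        for uR in uR_grid:
            circuit = make_autoregulated(
                params.with_inputs(u1R=uR, u2R=uR), p_x, u_tilde_A,
                variant=variant)
            net = circuit.qss_network
            if x is None:
                x = {"DA": 1.0, "D1R": 0.0, "D2R": 0.0, "D12R": 0.0}
            x = relax_to_steady_state(net, x, tau_relax=2e3)
            DA = float(x[net.index("DA")])
            rows.append({"p_x": p_x, "uR": uR, "DA": DA})
            if DA < threshold and not np.isfinite(crit[p_x]):
                crit[p_x] = float(uR)
    return pd.DataFrame(rows), crit
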