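"""Gillespie stochastic simulation of chromatin modification circuits.

Implements the direct method over any :class:`~chromem.model.ReactionNetwork`
(chromatin-only or protein-coupled), with three experiment layers used
throughout the package:

* :func:`stationary_histogram` — empirical stationary distribution of the
  chromatin state, pooled over independent replicates after burn-in;
* :func:`first_passage_sample` — hitting-time samples for "time to memory
  loss" experiments (repressed -> active and vice versa);
* :func:`reactivation_experiment` — latency of gene reactivation under an
  activating input.

All times are in normalized units ``tau = t * kMA * D_tot / Omega``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _kernel
from .model import ReactionNetwork
from .results import FirstPassageSamples, StationaryDistribution

__all__ = [
    "StopCondition",
    "SSARun",
    "ssa_run",
    "stationary_histogram",
    "first_passage_sample",
    "reactivation_experiment",
    "spawn_seeds",
]


def spawn_seeds(seed: int, n: int) -> np.ndarray:
    """Derive ``n`` independent 31-bit seeds from a master seed."""
    return np.random.SeedSequence(seed).generate_state(n) >> 1


@dataclass(frozen=True)
class StopCondition:
    """Linear threshold event ``sum_i w_i n_i  <=/>=  c``."""

    weights: tuple[tuple[str, float], ...]
    op: str           # "le" or "ge"
    threshold: float

    def __post_init__(self) -> None:
        if self.op not in ("le", "ge"):
            raise ValueError("op must be 'le' or 'ge'")

    @classmethod
    def on(cls, quantity: str, op: str, threshold: float,
           suffix: str = "") -> "StopCondition":
        """Build a stop condition on ``nA`` / ``nR`` / a species name.

        ``suffix`` selects a gene in two-gene circuits (e.g. ``":X"``).
        """
        if quantity == "nA":
            weights = ((f"DA{suffix}", 1.0),)
        elif quantity == "nR":
            weights = tuple((f"{s}{suffix}", 1.0) for s in ("D1R", "D2R", "D12R"))
        else:
            weights = ((quantity, 1.0),)
        return cls(weights, op, threshold)

    def vector(self, network: ReactionNetwork) -> tuple[np.ndarray, float, int]:
        w = np.zeros(network.n_species)
        for sp, v in self.weights:
            if sp in network.species:
                w[network.index(sp)] = v
        mode = 1 if self.op == "le" else 2
        return w, float(self.threshold), mode

    def holds(self, network: ReactionNetwork, n: np.ndarray) -> bool:
        w, c, mode = self.vector(network)
        val = float(w @ n)
        return val <= c if mode == 1 else val >= c


@dataclass
class SSARun:
    """One SSA realization: sampled states plus a bounded event log."""

    seed: int
    t_end: float
    status: str               # "tmax" | "stopped" | "absorbed"
    state_end: np.ndarray
    species: tuple[str, ...]
    sample_times: np.ndarray | None = None
    samples: np.ndarray | None = None
    event_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    event_reactions: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    n_events: int = 0

    def trajectory(self) -> pd.DataFrame:
        if self.samples is None:
            raise ValueError("run was not sampled")
        df = pd.DataFrame(self.samples, columns=list(self.species))
        df.insert(0, "tau", self.sample_times)
        return df


_STATUS = {_kernel.REACHED_TMAX: "tmax", _kernel.STOPPED: "stopped",
           _kernel.ABSORBED: "absorbed"}


def ssa_run(network: ReactionNetwork, init, t_max: float, seed: int,
            sample_times: np.ndarray | None = None,
            stop: StopCondition | None = None,
            max_event_log: int = 0, t0: float = 0.0,
            validate: bool = True) -> SSARun:
    """Simulate one exact realization of the network's CTMC.

    ``init`` is a ChromatinState / mapping / count vector.  The run ends at
    ``t_max``, at the first time ``stop`` holds, or in an absorbing state
    (zero total propensity, reported, not an error).  Fixed seeds reproduce
    the event sequence exactly.
    """
    n = network.state_array(init).copy()
    if validate:
        network.validate_state(n)
    sub_idx, coeff, S, cat, hill_K, hill_h = network.arrays()
    if stop is not None:
        stop_w, stop_c, stop_mode = stop.vector(network)
    else:
        stop_w, stop_c, stop_mode = np.zeros(network.n_species), 0.0, 0
    ev_t = np.zeros(max(max_event_log, 1))
    ev_r = np.zeros(max(max_event_log, 1), dtype=np.int64)
    if sample_times is not None:
        st = np.asarray(sample_times, dtype=float)
        samples = np.zeros((len(st), network.n_species), dtype=np.int64)
        t_end, status, n_filled, n_ev, _ = _kernel.ssa_core_sampling(
            n, float(t0), float(t_max), sub_idx, coeff, S, cat, hill_K,
            hill_h, float(network.D_tot), stop_w, stop_c, stop_mode, st,
            samples, ev_t, ev_r, int(seed))
        samples = samples[:n_filled]
        st = st[:n_filled]
    else:
        t_end, status, n_ev, _ = _kernel.ssa_core(
            n, float(t0), float(t_max), sub_idx, coeff, S, cat, hill_K,
            hill_h, float(network.D_tot), stop_w, stop_c, stop_mode,
            ev_t, ev_r, int(seed))
        samples, st = None, None
    return SSARun(seed=int(seed), t_end=float(t_end), status=_STATUS[status],
                  state_end=n, species=network.species, sample_times=st,
                  samples=samples, event_times=ev_t[:n_ev],
                  event_reactions=ev_r[:n_ev], n_events=n_ev)


def stationary_histogram(network: ReactionNetwork, init, horizon: float,
                         reps: int, seed: int, burn_in: float | None = None,
                         samples_per_rep: int = 200,
                         margin: int = 6) -> StationaryDistribution:
    """Empirical stationary distribution pooled over independent runs.

    Each replicate starts from ``init`` (a single state or a list cycled
    over), runs to ``horizon``, discards ``burn_in`` (default 20% of the
    horizon) and contributes ``samples_per_rep`` equispaced state samples.
    Warns when one of the two macro-states (``nA >= D_tot - margin`` /
    ``nR >= D_tot - margin``) is never visited, which suggests the pooled
    histogram has not mixed.
    """
    if burn_in is None:
        burn_in = 0.2 * horizon
    inits = init if isinstance(init, (list, tuple)) else [init]
    seeds = spawn_seeds(seed, reps)
    st = np.linspace(burn_in, horizon, samples_per_rep)
    counts: dict[tuple, int] = {}
    for i in range(reps):
        run = ssa_run(network, inits[i % len(inits)], horizon, seeds[i],
                      sample_times=st)
        for row in run.samples:
            key = tuple(int(v) for v in row)
            counts[key] = counts.get(key, 0) + 1
    states = np.array(sorted(counts), dtype=np.int64)
    probs = np.array([counts[tuple(s)] for s in states], dtype=float)
    dist = StationaryDistribution(states, probs, network.species,
                                  metadata={"engine": "ssa", "reps": reps,
                                            "horizon": horizon,
                                            "burn_in": burn_in, "seed": seed,
                                            "samples_per_rep": samples_per_rep}
                                  ).normalize()
    if "DA" in network.species:
        hi = network.D_tot - margin
        active = dist.mass(lambda s: s.get("DA", 0) >= hi)
        rep = dist.mass(lambda s: s.get("D1R", 0) + s.get("D2R", 0)
                        + s.get("D12R", 0) >= hi)
        if active == 0.0 or rep == 0.0:
            warnings.warn(
                "one chromatin macro-state was never sampled; the histogram "
                "may not have mixed", stacklevel=2)
    return dist


def first_passage_sample(network: ReactionNetwork, start,
                         target: StopCondition, reps: int, max_time: float,
                         seed: int) -> FirstPassageSamples:
    """i.i.d. first-hitting times of ``target`` from ``start``.

    Replicates that reach ``max_time`` without hitting are censored: they are
    excluded from the mean but reported (``n_censored``); if all replicates
    are censored the mean is NaN and ``lower_bound`` applies.
    """
    seeds = spawn_seeds(seed, reps)
    times = np.zeros(reps)
    censored = np.zeros(reps, dtype=bool)
    for i in range(reps):
        run = ssa_run(network, start, max_time, seeds[i], stop=target)
        times[i] = run.t_end
        censored[i] = run.status != "stopped"
    start_map = dict(zip(network.species,
                         (int(v) for v in network.state_array(start))))
    fps = FirstPassageSamples(times, censored, start_map,
                              f"{target.weights} {target.op} {target.threshold}",
                              metadata={"seed": seed, "max_time": max_time})
    if fps.n_censored == reps:
        warnings.warn("all replicates censored; mean undefined, reporting "
                      "lower bound only", stacklevel=2)
    return fps


def reactivation_experiment(network: ReactionNetwork, start, reps: int,
                            seed: int, max_time: float, margin: int = 6,
                            n_traj: int = 0, traj_samples: int = 200):
    """Reactivation latency: first time ``nA`` reaches ``D_tot - margin``.

    ``network`` should already carry the activating input ``uA`` in its
    drive coefficients.  Returns ``(latency_samples, trajectories)`` where
    the optional trajectories are sampled runs of the first ``n_traj``
    replicate seeds (for switch-like behaviour inspection).
    """
    target = StopCondition.on("nA", "ge", network.D_tot - margin)
    latencies = first_passage_sample(network, start, target, reps, max_time, seed)
    trajectories = []
    if n_traj > 0:
        seeds = spawn_seeds(seed, reps)
        st = np.linspace(0.0, max_time, traj_samples)
        for i in range(min(n_traj, reps)):
            trajectories.append(ssa_run(network, start, max_time, seeds[i],
                                        sample_times=st))
    return latencies, trajectories
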