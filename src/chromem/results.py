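"""Result containers shared by the stochastic and exact-Markov engines."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["StationaryDistribution", "FirstPassageSamples", "FirstPassageResult"]


@dataclass
class StationaryDistribution:
    """Probability mass over chromatin states, exact or empirical.

    ``states`` enumerates the support (rows of integer counts over
    ``species``); ``probs`` the matching probabilities.  ``metadata`` records
    provenance (engine, protocol, seed, parameters).
    """

    states: np.ndarray
    probs: np.ndarray
    species: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states)
        self.probs = np.asarray(self.probs, dtype=float)
        if len(self.states) != len(self.probs):
            raise ValueError("states/probs length mismatch")

    def normalize(self) -> "StationaryDistribution":
        self.probs = self.probs / self.probs.sum()
        return self

    def marginal(self, weight_map: Mapping[str, Mapping[str, float]],
                 shape: tuple[int, ...]) -> np.ndarray:
        """Histogram over derived integer coordinates.

        ``weight_map`` maps output axis name -> {species: weight}; e.g.
        ``{"nA": {"DA": 1}, "nR": {"D1R": 1, "D2R": 1, "D12R": 1}}``.
        """
        coords = []
        for _, weights in weight_map.items():
            w = np.zeros(len(self.species))
            for sp, v in weights.items():
                w[self.species.index(sp)] = v
            coords.append(np.rint(self.states @ w).astype(int))
        out = np.zeros(shape)
        np.add.at(out, tuple(coords), self.probs)
        return out

    def marginal_nA_nR(self, D_tot: int, suffix: str = "") -> np.ndarray:
        """(nA, nR) joint mass on a (D_tot+1) x (D_tot+1) grid."""
        rep = [s for s in (f"D1R{suffix}", f"D2R{suffix}", f"D12R{suffix}")
               if s in self.species]
        wmap = {"nA": {f"DA{suffix}": 1.0}, "nR": {s: 1.0 for s in rep}}
        return self.marginal(wmap, (D_tot + 1, D_tot + 1))

    def mass(self, predicate) -> float:
        """Total probability of states satisfying ``predicate(counts_dict)``."""
        total = 0.0
        for s, p in zip(self.states, self.probs):
            if predicate(dict(zip(self.species, s))):
                total += p
        return float(total)

    def prob_of(self, state: Mapping[str, int]) -> float:
        vec = np.array([state.get(s, 0) for s in self.species])
        hits = np.all(self.states == vec, axis=1)
        return float(self.probs[hits].sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(self.species))
        df["probability"] = self.probs
        return df

    def total_variation(self, other: "StationaryDistribution") -> float:
        """TV distance on the union support (species sets must match)."""
        if tuple(self.species) != tuple(other.species):
            raise ValueError("species mismatch")
        table: dict[tuple, float] = {}
        for s, p in zip(self.states, self.probs):
            table[tuple(s)] = table.get(tuple(s), 0.0) + p
        for s, p in zip(other.states, other.probs):
            table[tuple(s)] = table.get(tuple(s), 0.0) - p
        return 0.5 * sum(abs(v) for v in table.values())


@dataclass
class FirstPassageSamples:
    """SSA first-hitting-time samples for a start state / target predicate."""

    times: np.ndarray          # per-replicate hitting times (normalized)
    censored: np.ndarray       # True where max_time was reached before the hit
    start: dict
    target: str
    metadata: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.times)

    @property
    def n_censored(self) -> int:
        return int(self.censored.sum())

    @property
    def mean(self) -> float:
        """Mean over uncensored replicates (the time to memory loss)."""
        t = self.times[~self.censored]
        if len(t) == 0:
            return float("nan")
        return float(t.mean())

    @property
    def se(self) -> float:
        t = self.times[~self.censored]
        if len(t) < 2:
            return float("nan")
        return float(t.std(ddof=1) / np.sqrt(len(t)))

    @property
    def cv(self) -> float:
        t = self.times[~self.censored]
        if len(t) < 2 or t.mean() == 0:
            return float("nan")
        return float(t.std(ddof=1) / t.mean())

    @property
    def lower_bound(self) -> float:
        """Mean computed with censored replicates at max_time (a lower bound)."""
        return float(self.times.mean())

    def summary(self) -> dict:
        return {"mean": self.mean, "se": self.se, "cv": self.cv,
                "n": self.n, "n_censored": self.n_censored}


@dataclass
class FirstPassageResult:
    """Exact mean first-passage times (one entry per start state)."""

    mfpt: np.ndarray           # expected hitting time per state (inf if unreachable)
    target_mask: np.ndarray    # True on target states
    metadata: dict = field(default_factory=dict)
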