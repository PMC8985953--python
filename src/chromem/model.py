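"""Core reaction-network model of the gene's inner chromatin modification circuit.

The circuit tracks a pool of ``D_tot`` nucleosomes, each in one of five
modification states:

``D``
    unmodified nucleosome,
``DA``
    activating histone modification (H3K4me3/ac),
``D1R``
    DNA methylation only (CpGme),
``D2R``
    repressive histone methylation only (H3K9me2/3),
``D12R``
    both CpGme and H3K9me3.

Activating marks are mutually exclusive with both repressive marks; CpGme and
H3K9me3 can co-exist.  Reactions fall into four classes: de novo
establishment (TF-driven or basal writing), auto-catalysis (a mark recruiting
writers of itself), cross-catalysis (CpGme and H3K9me3 reinforcing each
other), and basal or recruited erasure (dilution/non-specific removal vs
erasers recruited by the opposing mark).

All dynamics are expressed in normalized time ``tau = t * kMA * Dtot/Omega``
and in the dimensionless parameter set built by :func:`nondimensionalize`:

``alpha, alpha_bar, alpha_prime``
    auto-/cross-catalysis rates relative to the activating auto-catalysis,
``eps``
    basal erasure relative to catalysis (the key time-scale separation knob),
``eps_prime``
    recruited erasure relative to catalysis,
``mu, mu_prime``
    erasure of repressive histone marks / DNA methylation relative to the
    erasure of activating marks,
``u*``
    normalized writing inputs (basal ``u0A, u10R, u20R`` and TF-driven
    ``uA, u1R, u2R``).

The single :class:`ReactionNetwork` produced by :func:`build_network` is the
source of truth for the deterministic (ODE), exact-Markov (CME) and
stochastic (SSA) engines.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "RateConstants",
    "DimensionlessParams",
    "ChromatinState",
    "Reaction",
    "ReactionNetwork",
    "nondimensionalize",
    "dimensionalize",
    "build_network",
    "CHROMATIN_SPECIES",
    "HISTONE_SPECIES",
]

#: chromatin species of the full circuit, in canonical order
CHROMATIN_SPECIES = ("D", "DA", "D1R", "D2R", "D12R")
#: chromatin species of the histone-modification-only sub-circuit
HISTONE_SPECIES = ("D", "DA", "D2R")


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RateConstants:
    """Dimensional rate constants (units: 1/time, or 1/(conc*time) for
    catalysis and recruited erasure).

    ``kMA`` is the activating auto-catalysis rate constant and serves as the
    normalization; it must be positive.
    """

    kMA: float  # activating auto-catalysis, 1/(conc*time)
    kM: float = 0.0  # repressive-histone auto-catalysis
    kM_bar: float = 0.0  # CpGme -> H3K9me cross-catalysis
    kM_prime: float = 0.0  # H3K9me -> CpGme cross-catalysis
    kW0A: float = 0.0  # basal de novo writing of the activating mark, 1/time
    kW01: float = 0.0  # basal de novo CpG methylation
    kW02: float = 0.0  # basal de novo H3K9 methylation
    kWA: float = 0.0  # TF-driven writing of the activating mark
    kW1: float = 0.0  # TF-driven CpG methylation
    kW2: float = 0.0  # TF-driven H3K9 methylation
    kEA_bar: float = 0.0  # basal active erasure of the activating mark, 1/time
    kER_bar: float = 0.0  # basal active erasure of H3K9me
    kEA: float = 0.0  # recruited erasure of the activating mark, 1/(conc*time)
    kER: float = 0.0  # recruited erasure of H3K9me
    kT_prime: float = 0.0  # basal DNA de-methylation (TET-mediated), 1/time
    kT_star: float = 0.0  # recruited DNA de-methylation, 1/(conc*time)
    delta: float = 0.0  # dilution rate constant, 1/time
    delta_prime: float = 0.0  # dilution of CpGme (delta * eta)
    alpha_x: float = 0.0  # protein production per DA nucleosome, 1/time
    gamma_x: float = 0.0  # protein decay, 1/time
    Omega: float = 1.0  # reaction volume
    D_tot: int = 50  # total nucleosome count

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if name in ("Omega", "D_tot"):
                continue
            if value < 0:
                raise ValueError(f"rate constant {name} must be >= 0, got {value}")
        if self.kMA <= 0:
            raise ValueError("kMA must be > 0 (it is the normalization)")
        if self.Omega <= 0:
            raise ValueError("Omega must be > 0")
        if self.D_tot < 2:
            raise ValueError("D_tot must be an integer >= 2")

    @property
    def conc_total(self) -> float:
        """Total nucleosome concentration D_tot/Omega."""
        return self.D_tot / self.Omega


@dataclass(frozen=True)
class DimensionlessParams:
    """Dimensionless parameterization of the circuit.

    Time is normalized by the activating auto-catalysis rate
    (``tau = t * kMA * D_tot/Omega``); every coefficient below is a rate in
    that normalized time.
    """

    alpha: float = 1.0
    alpha_bar: float = 1.0
    alpha_prime: float = 1.0
    eps: float = 1.0
    eps_prime: float = 1.0
    mu: float = 1.0
    mu_prime: float = 1.0
    b: float = 1.0
    beta: float = 1.0
    u0A: float = 0.0
    u10R: float = 0.0
    u20R: float = 0.0
    uA: float = 0.0
    u1R: float = 0.0
    u2R: float = 0.0
    p_x: float = 0.0
    gamma_x_bar: float = 0.0
    D_tot: int = 50

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if name == "D_tot":
                continue
            if value < 0:
                raise ValueError(f"parameter {name} must be >= 0, got {value}")
        if self.D_tot < 2:
            raise ValueError("D_tot must be an integer >= 2")

    # derived input aggregates
    @property
    def u_bar_A(self) -> float:
        return self.u0A + self.uA

    @property
    def u_bar_1R(self) -> float:
        return self.u10R + self.u1R

    @property
    def u_bar_2R(self) -> float:
        return self.u20R + self.u2R

    @property
    def u_bar_12R(self) -> float:
        return self.u_bar_1R + self.u_bar_2R

    def with_inputs(self, uA: float | None = None, u1R: float | None = None,
                    u2R: float | None = None) -> "DimensionlessParams":
        """Copy with external inputs replaced (basal inputs untouched)."""
        kwargs = {}
        if uA is not None:
            kwargs["uA"] = uA
        if u1R is not None:
            kwargs["u1R"] = u1R
        if u2R is not None:
            kwargs["u2R"] = u2R
        return replace(self, **kwargs)

    def replace(self, **kwargs) -> "DimensionlessParams":
        return replace(self, **kwargs)


@dataclass
class ChromatinState:
    """Integer nucleosome counts, optionally with protein copy numbers."""

    nA: int
    n1R: int
    n2R: int
    n12R: int
    nD: int
    nX: int | None = None
    nZ: int | None = None

    def __post_init__(self) -> None:
        for name in ("nA", "n1R", "n2R", "n12R", "nD"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("nX", "nZ"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def nR(self) -> int:
        """Total repressed nucleosomes n1R + n2R + n12R."""
        return self.n1R + self.n2R + self.n12R

    @property
    def D_tot(self) -> int:
        return self.nA + self.n1R + self.n2R + self.n12R + self.nD

    @classmethod
    def from_mapping(cls, counts: Mapping[str, int]) -> "ChromatinState":
        return cls(
            nA=counts.get("DA", 0),
            n1R=counts.get("D1R", 0),
            n2R=counts.get("D2R", 0),
            n12R=counts.get("D12R", 0),
            nD=counts.get("D", 0),
            nX=counts.get("X"),
            nZ=counts.get("Z"),
        )

    def to_mapping(self) -> dict[str, int]:
        out = {"D": self.nD, "DA": self.nA, "D1R": self.n1R,
               "D2R": self.n2R, "D12R": self.n12R}
        if self.nX is not None:
            out["X"] = self.nX
        if self.nZ is not None:
            out["Z"] = self.nZ
        return out


# ---------------------------------------------------------------------------
# reactions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Reaction:
    """One elementary conversion or protein production/decay step.

    Propensity convention in normalized time:

    * non-catalysed: ``coefficient * n[substrate]``
    * catalysed: ``coefficient * n[substrate] * (sum of catalyst counts) / D_tot``

    ``stoich`` maps species names to integer count changes.  ``hill`` is
    ``None`` for the default linear catalyst dependence, or ``(K, h)`` for a
    Hill saturation of the catalyst *fraction*.
    """

    label: str
    substrate: str
    stoich: tuple[tuple[str, int], ...]
    catalysts: tuple[str, ...]
    coefficient: float
    hill: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.coefficient < 0:
            raise ValueError(f"reaction {self.label}: coefficient must be >= 0")

    @staticmethod
    def convert(label: str, frm: str, to: str, coefficient: float,
                catalysts: Sequence[str] = ()) -> "Reaction":
        return Reaction(label=label, substrate=frm,
                        stoich=((frm, -1), (to, +1)),
                        catalysts=tuple(catalysts), coefficient=coefficient)


class ReactionNetwork:
    """Species list + reactions; shared by the ODE, CME and SSA engines."""

    def __init__(self, species: Sequence[str], reactions: Sequence[Reaction],
                 D_tot: int, variant: str,
                 conserved_groups: Sequence[Sequence[str]] | None = None,
                 params: DimensionlessParams | None = None):
        self.species = tuple(species)
        self.reactions = tuple(reactions)
        self.D_tot = int(D_tot)
        self.variant = variant
        self.params = params
        if conserved_groups is None:
            conserved_groups = [tuple(s for s in species if not s.startswith(("X", "Z")))]
        self.conserved_groups = tuple(tuple(g) for g in conserved_groups)
        self._index = {s: i for i, s in enumerate(self.species)}
        self._check()
        self._arrays_cache: tuple | None = None

    # -- validation ---------------------------------------------------------
    def _check(self) -> None:
        for r in self.reactions:
            if r.substrate not in self._index:
                raise ValueError(f"reaction {r.label}: unknown substrate {r.substrate}")
            for sp, _ in r.stoich:
                if sp not in self._index:
                    raise ValueError(f"reaction {r.label}: unknown species {sp}")
            for c in r.catalysts:
                if c not in self._index:
                    raise ValueError(f"reaction {r.label}: unknown catalyst {c}")
            for group in self.conserved_groups:
                change = sum(d for sp, d in r.stoich if sp in group)
                if change != 0:
                    raise ValueError(
                        f"reaction {r.label} breaks nucleosome conservation in {group}")

    def index(self, species: str) -> int:
        return self._index[species]

    @property
    def n_species(self) -> int:
        return len(self.species)

    # -- array views --------------------------------------------------------
    def arrays(self):
        """(sub_idx, coeff, S, cat_mat, hill_K, hill_h) as contiguous arrays.

        ``S`` is the (n_reactions, n_species) stoichiometry matrix;
        ``cat_mat[r]`` is a 0/1 indicator over species (all-zero for
        non-catalysed reactions); ``hill_h[r] == 0`` means linear catalyst
        dependence.
        """
        if self._arrays_cache is None:
            R, Ns = len(self.reactions), self.n_species
            sub_idx = np.zeros(R, dtype=np.int64)
            coeff = np.zeros(R)
            S = np.zeros((R, Ns), dtype=np.int64)
            cat = np.zeros((R, Ns))
            hill_K = np.zeros(R)
            hill_h = np.zeros(R)
            for i, r in enumerate(self.reactions):
                sub_idx[i] = self._index[r.substrate]
                coeff[i] = r.coefficient
                for sp, d in r.stoich:
                    S[i, self._index[sp]] += d
                for c in r.catalysts:
                    cat[i, self._index[c]] = 1.0
                if r.hill is not None:
                    hill_K[i], hill_h[i] = r.hill
            self._arrays_cache = (sub_idx, coeff, S, cat, hill_K, hill_h)
        return self._arrays_cache

    # -- state conversion ---------------------------------------------------
    def state_array(self, state) -> np.ndarray:
        """Convert a mapping / ChromatinState / sequence to a count vector."""
        if isinstance(state, ChromatinState):
            state = state.to_mapping()
        if isinstance(state, Mapping):
            vec = np.zeros(self.n_species, dtype=np.int64)
            for sp, v in state.items():
                vec[self._index[sp]] = v
            return vec
        arr = np.asarray(state, dtype=np.int64)
        if arr.shape != (self.n_species,):
            raise ValueError("state vector has wrong length")
        return arr

    def validate_state(self, n: np.ndarray) -> None:
        if np.any(n < 0):
            raise ValueError("negative species count")
        for group in self.conserved_groups:
            total = sum(int(n[self._index[s]]) for s in group)
            if total != self.D_tot:
                raise ValueError(
                    f"counts over {group} sum to {total}, expected D_tot={self.D_tot}")

    # -- dynamics -----------------------------------------------------------
    def propensities(self, n: np.ndarray) -> np.ndarray:
        """Reaction propensities at integer state ``n`` (normalized time)."""
        sub_idx, coeff, _, cat, hill_K, hill_h = self.arrays()
        a = coeff * n[sub_idx]
        has_cat = cat.any(axis=1)
        if has_cat.any():
            frac = (cat @ n) / self.D_tot
            factor = np.where(has_cat, frac, 1.0)
            hill = hill_h > 0
            if hill.any():
                with np.errstate(divide="ignore", invalid="ignore"):
                    fh = frac ** hill_h
                    factor = np.where(hill, fh / (hill_K ** hill_h + fh), factor)
                factor = np.nan_to_num(factor)
            a = a * factor
        return a

    def mean_field(self, x: np.ndarray) -> np.ndarray:
        """Mass-action mean-field RHS in fraction variables.

        ``x`` holds fractions for chromatin species (and protein per-D_tot
        fractions for X/Z); the returned vector is d x / d tau.
        """
        sub_idx, coeff, S, cat, hill_K, hill_h = self.arrays()
        rates = coeff * x[sub_idx]
        has_cat = cat.any(axis=1)
        if has_cat.any():
            frac = cat @ x
            factor = np.where(has_cat, frac, 1.0)
            hill = hill_h > 0
            if hill.any():
                with np.errstate(divide="ignore", invalid="ignore"):
                    fh = frac ** hill_h
                    factor = np.where(hill, fh / (hill_K ** hill_h + fh), factor)
                factor = np.nan_to_num(factor)
            rates = rates * factor
        return rates @ S

    # -- serialization ------------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "species": list(self.species),
            "variant": self.variant,
            "D_tot": self.D_tot,
            "conserved_groups": [list(g) for g in self.conserved_groups],
            "reactions": [
                {
                    "label": r.label,
                    "substrate": r.substrate,
                    "stoich": {sp: d for sp, d in r.stoich},
                    "catalysts": list(r.catalysts),
                    "coefficient": r.coefficient,
                    **({"hill": list(r.hill)} if r.hill else {}),
                }
                for r in self.reactions
            ],
            "params": asdict(self.params) if self.params is not None else None,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ReactionNetwork":
        payload = json.loads(text)
        reactions = [
            Reaction(
                label=r["label"],
                substrate=r["substrate"],
                stoich=tuple(sorted(r["stoich"].items())),
                catalysts=tuple(r["catalysts"]),
                coefficient=r["coefficient"],
                hill=tuple(r["hill"]) if r.get("hill") else None,
            )
            for r in payload["reactions"]
        ]
        params = (DimensionlessParams(**payload["params"])
                  if payload.get("params") else None)
        return cls(payload["species"], reactions, payload["D_tot"],
                   payload["variant"], payload["conserved_groups"], params)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"ReactionNetwork(variant={self.variant!r}, "
                f"species={len(self.species)}, reactions={len(self.reactions)}, "
                f"D_tot={self.D_tot})")


# ---------------------------------------------------------------------------
# parameter maps
# ---------------------------------------------------------------------------


def nondimensionalize(rates: RateConstants) -> DimensionlessParams:
    """Map dimensional rate constants to the dimensionless parameter set.

    Raises ``ValueError`` when a ratio is undefined (``kEA == 0`` while a
    recruited-erasure constant is positive, or a basal repressive erasure
    without any basal activating erasure, which makes ``b``/``beta``
    unrepresentable).
    """
    Dc = rates.conc_total
    norm = rates.kMA * Dc
    if rates.kEA == 0.0 and (rates.kER > 0.0 or rates.kT_star > 0.0):
        raise ValueError("kEA = 0 with kER or kT_star > 0: mu/mu_prime undefined")
    mu = rates.kER / rates.kEA if rates.kEA > 0 else 0.0
    mu_prime = rates.kT_star / rates.kEA if rates.kEA > 0 else 0.0
    basal_A = rates.delta + rates.kEA_bar
    basal_R = rates.delta + rates.kER_bar
    basal_T = rates.delta_prime + rates.kT_prime

    def _scale(numer: float, denom: float, name: str) -> float:
        if denom == 0.0:
            if numer == 0.0:
                return 1.0
            raise ValueError(
                f"{name} undefined: basal repressive erasure with "
                "zero (delta + kEA_bar) * ratio")
        return numer / denom

    b = _scale(basal_R, basal_A * mu, "b")
    beta = _scale(basal_T, basal_A * mu_prime, "beta")
    return DimensionlessParams(
        alpha=rates.kM / rates.kMA,
        alpha_bar=rates.kM_bar / rates.kMA,
        alpha_prime=rates.kM_prime / rates.kMA,
        eps=basal_A / norm,
        eps_prime=rates.kEA / rates.kMA,
        mu=mu,
        mu_prime=mu_prime,
        b=b,
        beta=beta,
        u0A=rates.kW0A / norm,
        u10R=rates.kW01 / norm,
        u20R=rates.kW02 / norm,
        uA=rates.kWA / norm,
        u1R=rates.kW1 / norm,
        u2R=rates.kW2 / norm,
        p_x=(rates.alpha_x / rates.gamma_x) if rates.gamma_x > 0 else 0.0,
        gamma_x_bar=rates.gamma_x / norm,
        D_tot=rates.D_tot,
    )


def dimensionalize(params: DimensionlessParams, kMA: float, Omega: float = 1.0,
                   dilution_fraction: float = 0.0) -> RateConstants:
    """Inverse of :func:`nondimensionalize` for fixed ``kMA`` and ``Omega``.

    By convention all basal erasure is attributed to enzymatic constants
    (``delta = 0``) unless ``dilution_fraction`` in (0, 1] assigns that
    fraction of the basal activating erasure to dilution.  Only the sums
    ``delta + kEA_bar`` etc. are dynamically meaningful.
    """
    if kMA <= 0:
        raise ValueError("kMA must be > 0")
    if not 0.0 <= dilution_fraction <= 1.0:
        raise ValueError("dilution_fraction must be in [0, 1]")
    Dc = params.D_tot / Omega
    norm = kMA * Dc
    basal_A = params.eps * norm
    delta = dilution_fraction * basal_A
    basal_R = params.b * params.mu * basal_A
    if basal_R < delta:
        raise ValueError("dilution_fraction too large for the repressive basal erasure")
    kEA = params.eps_prime * kMA
    gamma_x = params.gamma_x_bar * norm
    return RateConstants(
        kMA=kMA,
        kM=params.alpha * kMA,
        kM_bar=params.alpha_bar * kMA,
        kM_prime=params.alpha_prime * kMA,
        kW0A=params.u0A * norm,
        kW01=params.u10R * norm,
        kW02=params.u20R * norm,
        kWA=params.uA * norm,
        kW1=params.u1R * norm,
        kW2=params.u2R * norm,
        kEA_bar=basal_A - delta,
        kER_bar=basal_R - delta,
        kEA=kEA,
        kER=params.mu * kEA,
        kT_prime=params.beta * params.mu_prime * basal_A,
        kT_star=params.mu_prime * kEA,
        delta=delta,
        delta_prime=0.0,
        alpha_x=params.p_x * gamma_x,
        gamma_x=gamma_x,
        Omega=Omega,
        D_tot=params.D_tot,
    )


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

# catalyst sets
_A = ("DA",)
_K9 = ("D2R", "D12R")
_ME = ("D1R", "D12R")


def build_network(params: DimensionlessParams, variant: str = "full", *,
                  merge_recruited_erasure: bool = False,
                  overrides: Mapping[str, float] | None = None) -> ReactionNetwork:
    """Construct the chromatin reaction network for a circuit variant.

    ``variant="full"`` includes DNA methylation; ``variant="histone_only"``
    keeps only {D, DA, D2R} and the histone reactions, the classic
    two-mark competition sub-circuit.

    ``merge_recruited_erasure=True`` collapses the K9- and CpGme-recruited
    erasure of DA into a single reaction whose catalyst set is the union
    {D1R, D2R, D12R}, so a doubly marked nucleosome catalyses erasure once
    instead of twice.  ``overrides`` maps reaction labels to replacement
    coefficients.
    """
    p = params
    conv = Reaction.convert
    if variant == "full":
        rxns = [
            # de novo establishment
            conv("0+1", "D", "DA", p.u_bar_A),
            conv("2", "D", "D2R", p.u_bar_2R),
            conv("3", "D1R", "D12R", p.u_bar_2R),
            conv("10", "D", "D1R", p.u_bar_1R),
            conv("11", "D2R", "D12R", p.u_bar_1R),
            # auto-catalysis
            conv("4", "D", "DA", 1.0, _A),
            conv("5a", "D", "D2R", p.alpha, _K9),
            conv("5b", "D1R", "D12R", p.alpha, _K9),
            # cross-catalysis
            conv("15a", "D", "D2R", p.alpha_bar, _ME),
            conv("15b", "D1R", "D12R", p.alpha_bar, _ME),
            conv("16a", "D", "D1R", p.alpha_prime, _K9),
            conv("16b", "D2R", "D12R", p.alpha_prime, _K9),
            # basal erasure
            conv("6", "DA", "D", p.eps),
            conv("7a", "D2R", "D", p.b * p.eps * p.mu),
            conv("7b", "D12R", "D1R", p.b * p.eps * p.mu),
            conv("12a", "D1R", "D", p.beta * p.eps * p.mu_prime),
            conv("12b", "D12R", "D2R", p.beta * p.eps * p.mu_prime),
            # recruited erasure
            conv("8a", "D2R", "D", p.mu * p.eps_prime, _A),
            conv("8b", "D12R", "D1R", p.mu * p.eps_prime, _A),
            conv("14a", "D1R", "D", p.mu_prime * p.eps_prime, _A),
            conv("14b", "D12R", "D2R", p.mu_prime * p.eps_prime, _A),
        ]
        if merge_recruited_erasure:
            rxns.append(conv("9+13", "DA", "D", p.eps_prime, ("D1R", "D2R", "D12R")))
        else:
            rxns.append(conv("9", "DA", "D", p.eps_prime, _K9))
            rxns.append(conv("13", "DA", "D", p.eps_prime, _ME))
        species = CHROMATIN_SPECIES
    elif variant == "histone_only":
        rxns = [
            conv("0+1", "D", "DA", p.u_bar_A),
            conv("2", "D", "D2R", p.u_bar_2R),
            conv("4", "D", "DA", 1.0, _A),
            conv("5a", "D", "D2R", p.alpha, ("D2R",)),
            conv("6", "DA", "D", p.eps),
            conv("7a", "D2R", "D", p.b * p.eps * p.mu),
            conv("8a", "D2R", "D", p.mu * p.eps_prime, _A),
            conv("9", "DA", "D", p.eps_prime, ("D2R",)),
        ]
        species = HISTONE_SPECIES
    else:
        raise ValueError(f"unknown circuit variant {variant!r}")

    if overrides:
        labels = {r.label for r in rxns}
        unknown = set(overrides) - labels
        if unknown:
            raise ValueError(f"override for unknown reaction labels: {sorted(unknown)}")
        rxns = [
            replace(r, coefficient=overrides.get(r.label, r.coefficient))
            for r in rxns
        ]
    return ReactionNetwork(species, rxns, p.D_tot, variant,
                           conserved_groups=[species], params=p)
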