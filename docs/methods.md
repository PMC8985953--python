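# Methods

## Model

The unit of state is the nucleosome.  A gene carries `D_tot` nucleosomes,
each unmodified (`D`), activation-marked (`DA`, lumping H3K4me3 with
acetylation), DNA-methylated (`D1R`), H3K9-methylated (`D2R`), or doubly
repressed (`D12R`).  Assumptions inherited from the biology: H3K4 and H3K9
methylation are mutually exclusive on a nucleosome; CpG methylation
co-exists with H3K9me3 but not with the activating mark; me2/me3 are
lumped; each nucleosome carries at most one histone modification (no
two-tail bookkeeping); the pool is well mixed (no spatial arrangement —
any modified nucleosome can act on any other within the gene).

All reactions are one-step conversions with mass-action propensities in
normalized time `τ = t·k_M^A·𝒟_tot` (`𝒟_tot = D_tot/Ω`):

* non-catalysed: `coefficient × n_substrate`;
* catalysed: `coefficient × n_substrate × n_catalyst / D_tot`.

With this convention the SSA's mean-field limit equals the fraction-space
ODEs exactly, so one reaction list drives all three engines.  The
K9-recruited and CpGme-recruited erasures of the activating mark are kept
as separate reactions sharing the coefficient `ε′`, so a doubly marked
nucleosome contributes twice (they are mechanistically distinct eraser
recruitments); a `merge_recruited_erasure` switch collapses them to a
one-per-nucleosome weighting.  De novo and catalysed H3K9 methylation act
on `{D, D1R}` and CpG methylation on `{D, D2R}` with the same constants as
on `D` — mutual exclusivity makes `DA` never a methylation substrate, and
this substrate choice is what lets the doubly-repressed coordinate
`x = n12R` reach `D_tot`.

## Dimensionless parameters

| parameter | meaning | default |
|---|---|---|
| `α, ᾱ, α′` | H3K9 auto-catalysis and the two cross-catalyses, relative to activating auto-catalysis | 1 |
| `ε` | basal erasure of all marks vs catalysis | 1 |
| `ε′` | recruited erasure vs catalysis | 1 |
| `μ` | H3K9me erasure vs activating-mark erasure | 1 |
| `μ′` | CpGme erasure vs activating-mark erasure | 1 |
| `b, β` | order-one basal-erasure scale factors | 1 |
| `u0A, u10R, u20R` | basal writing inputs | 0 (0.1 in study conditions) |
| `uA, u1R, u2R` | TF-driven writing inputs | 0 |
| `p_x` | protein production/decay ratio (autoregulation gain) | 0 |

All rates are per normalized time; inputs are writing rates normalized by
`k_M^A·𝒟_tot`.  `dimensionalize` inverts the map with the convention that
basal erasure is attributed entirely to enzymatic constants (`δ = 0`)
unless a dilution fraction is supplied — only the sums `δ + k̄_E` are
dynamically meaningful.

The standard study condition throughout tests and the acceptance script is
basal inputs `0.1`, all ratios `1`, and `ε` as the control knob; `D_tot` is
50 for deterministic work and 8 (495 CME states) or 20 (two-gene SSA)
where exact or replicated stochastic computation must stay cheap.

## Deterministic engine

Stiff-capable integration (`LSODA`, rtol 1e-9/atol 1e-12) over all species
fractions; conservation is monitored rather than eliminated, and drifts
below 1e-8 over `τ = 1e4` in practice (measured ~1e-13).  Equilibria are
found by multistart Newton (Powell hybrid) from Dirichlet(1,…,1) samples
over each conserved simplex plus its vertices; half of the starts are
first relaxed along the flow for 25 time units so that attractors with
narrow Newton basins (notably the one-on/one-off patterns of the toggle
circuit) are reliably reached, while raw starts still land on unstable
equilibria.  Duplicates merge below 1e-6 sup-norm distance; stability is
classified by the leading finite-difference Jacobian eigenvalue with a
1e-8 margin (closer to zero → "marginal").  Saddle-node points in scans
are bisected to 1e-3 relative width.  Hysteresis sweeps are quasi-static:
at each input value the system is integrated for `τ = 1e3` (escalating
tenfold on failure) and Newton-polished; the polish is accepted only if it
stays within 0.1 of the integrated state, so it cannot jump branches.

## Stochastic engine

Direct-method Gillespie (no tau-leaping; the state spaces are tiny), with
the inner loop JIT-compiled by numba and a pure-Python twin used if the
JIT is unavailable.  Randomness is the legacy per-thread NumPy RNG seeded
per replicate from a `SeedSequence` of the user seed (31-bit), making
event logs exactly reproducible.  Stationary histograms pool many
independent replicates (default burn-in 20% of the horizon); replicates
are started from both extreme states so a non-mixing run is visible as a
warning when a macro-state goes unsampled.  First-passage experiments use
linear threshold stop conditions (`nA`/`nR` against a margin, default 6,
following the near-extreme stop convention of the memory-loss protocols);
censored replicates are reported and excluded from means.

## Exact Markov analysis

The CME state space enumerates compositions of `D_tot` over each conserved
group (full circuit: C(D_tot+4, 4) states).  Stationary laws solve
`πQ = 0, Σπ = 1` (dense least squares below 5000 states, residual checked
against 1e-10; reducible chains fall back to per-closed-class solutions
with a warning).  MFPTs solve the restricted system `Q_tt h = −1` by
sparse LU after a reachability check; starts that cannot reach the target
get `∞`.  MFPTs beyond ~1e15 normalized time units lose float64 accuracy
(observed as sign flips); monotonicity comparisons therefore use moderate
`ε` where values stay below ~1e12.

### One-dimensional reduction

Under time-scale separation (`ε, ε′` small) the slow coordinate is the
doubly-repressed count `x = n12R`.  For each level `x`, the x-preserving
reactions form the fast block; their exact conditional stationary law (a
small CME over compositions of `D_tot − x` into four parts) averages the
x-changing propensities into birth rates `λ(x)` and death rates `γ(x)` of
a birth–death chain (`λ(D_tot) = γ(0) = 0` by construction).  Stationary
law and hitting times then follow from standard product-form and recursion
formulas, evaluated in log space / by forward-backward recursions that
avoid cancellation.  The reduction reproduces the exact marginal over
`n12R` to total variation < 1e-3 at `ε = 1e-3, ε′ = 0.05, D_tot = 8`; a
warning is issued when `ε` or `ε′` exceeds 0.5.

### Closed-form small-`ε` limits

The limiting stationary law puts mass `1/(1+P)` on the fully active and
`P/(1+P)` on the fully repressed state, with `P` a product over levels
evaluated in log space.  The order-one per-level coefficients are supplied
as pluggable callables defaulting to 1: the limits (`P → ∞` as `ε → 0` or
`μμ′ → 0`) and every monotonicity used in tests (decreasing in `u^A` and
`p_x`, increasing in `u^R`) are invariant to those coefficients, so
nothing rests on their exact algebra.  The printed form of the product is
typographically ambiguous about numerator/denominator placement; the split
implemented here is the unique one consistent with the stated limits and
monotonicities (`μμ′`, `ε′`, `ε`, `b`, `β` and the activating drive in the
denominators; the repressive drive and catalysis terms in the numerators).
The memory-time laws `τ_R ≈ K_R/(μμ′ε²)·(…)` and `τ_A ≈ K_A/ε·(…)` are
likewise exposed with default coefficient/`h`-function stand-ins that
satisfy their stated structure (positive, increasing, vanishing at 0);
they are qualitative scaling laws, not fitted values.

### Memory-time power laws

The exponents (−2 for repressed→active, −1 for active→repressed on the
full circuit; −1/−1 on the histone-only sub-circuit) are asymptotic: the
minimal escape path from full repression needs exactly two basal-erasure
events (strip one nucleosome bare, at which point an activating nucleus
can recruit erasure for the rest), and higher-order basal paths stop
competing only once `ε` is well below the recruited-erasure scale.  The
scaling check therefore fits log–log slopes on `ε ∈ [1e-5, 1e-3]`
(`D_tot = 8`, exact MFPT), where the local slopes have converged; on
grids around `ε ~ 0.1` the measured slopes are steeper (≈ −4 to −8)
because multi-`ε` paths still dominate.

## Circuit composition

Gene expression is `DA → DA + X` at rate `ᾱ_x·nA` and decay `γ̄_x·nX`,
with `p_x = ᾱ_x/γ̄_x`.  Couplings are linear and zero-at-zero by default
(drive ∝ protein fraction `X̄ = nX/D_tot`); a Hill form is available.
Each motif exists in two exactly-corresponding representations:

* **explicit** — protein species with production/decay reactions (SSA and
  non-QSS ODE);
* **protein-QSS** — `X̄ = p_x·D̄A` substituted, which turns the
  autoregulation drive into an additional activating auto-catalysis of
  coefficient `ũ_A·p_x` and the mutual-repression drives into reactions
  catalysed by the opposing gene's `DA`.  This keeps the coupled circuits
  finite for CME/reduced-chain analysis and makes the equivalence
  "autoregulation = stronger activating auto-catalysis" an identity of the
  network rather than an approximation.

Explicit-protein simulations default to `γ̄_x = 1` (protein decay on the
chromatin catalysis time scale) with `ᾱ_x = p_x·γ̄_x`.  The TF-reset
robustness experiment uses `γ̄_x = 0.3` so that a reset produces a protein
outage lasting a few normalized time units — long enough that what carries
the pattern through the outage is the chromatin state, which is the
quantity under test; with instantaneous rebound the experiment cannot
distinguish `ε` regimes.  Protocol: `D_tot = 20`, `p = 5`, resets of both
proteins every 10 τ over 150 τ, 24 replicates.

## What the study conditions do and do not show

All experiments run on synthetic configurations of the model itself (the
package analyses a mechanistic model; there is no external data).  The
scaled-down sizes (`D_tot = 8–20` for stochastic work vs 50 for
deterministic sweeps) preserve every qualitative regime — bistability
windows, bimodality, memory asymmetry, toggle patterns — but absolute
first-passage times grow steeply with `D_tot`, so magnitudes reported at
small `D_tot` are not predictions for a 50-nucleosome gene.  Passing tests
demonstrate internal consistency of the three engines and the stated
parameter dependencies; they do not validate the biological rate constants,
the well-mixed assumption, or the lumping of me2/me3 and
transcription/translation.

## Known limitations

* No spatial/neighbour structure; catalysis is global within the gene.
* CME analysis requires chromatin-only networks; coupled circuits must go
  through the protein-QSS representation (explicit-protein chains are
  countably infinite).
* Branch tracking in `bifurcation_scan` is by stable-count change plus
  bisection, not pseudo-arclength continuation; folds that do not change
  the stable count between grid points would be missed on a too-coarse
  grid.
* Exact MFPTs above ~1e15 normalized time units are numerically unreliable
  (float64); use the reduced chain's recursions there.
* The one-dimensional reduction averages over the conditional stationary
  law of the fast block; at `ε′` comparable to catalysis it can misstate
  absolute exit times from the active side by large factors even when the
  stationary marginal is accurate — trends in `p_x`, `μμ′` and `ε` are
  robust, absolute values are not.
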