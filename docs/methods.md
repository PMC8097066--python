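# Methods

## Model

Cellulose hydrolysate is tracked over discrete molecular-mass classes.
For a chain of `n_units` cellobiose (CB) units the ladder is

* class `i` (chain classes): a fragment of `n_units − i` CB units with
  molar mass `342·u − 18·(u − 1)` g/mol — strictly decreasing, uniform
  324 g/mol spacing;
* a glucose class (180 g/mol) below the shortest chain class; and, in the
  `glucose_then_hmf` layout used for long chains under harsh conditions,
  an HMF class (126 g/mol by default) fed **only** from the glucose class.

The model is a homogeneous absorbing Markov chain: within one step `Δτ`, a
class-`i` chain survives with probability `P_ii` or cleaves once into two
descendants, the tracked one landing `d = j − i` classes lower with
probability `P_ji = f(d)`.  Each cleavage takes up one water (18 g/mol);
the state vector `ω` is kept on an anhydro-mass basis so that it remains a
probability vector (`Σω = 1`), which is what the per-step matrix update
`ω ← P ω` preserves.  Columns of `P` are source classes (the matrix is
lower triangular, `P_NN = 1` absorbing).

Two scission families are implemented, with parameters tied to the jump
support through `k = N + 1 − x`:

* **Gauss** `f_GS` with `μ = k/2`, `σ² = (k² − 1)/12` — mid-chain
  scission.  `σ²` is exactly the variance of the discrete uniform on
  `1..k`; `μ` is the midpoint of `0..k` (half a unit below the uniform
  mean — the printed map, kept as such).
* **Weibull** `f_W` with `λ = 1.4 + μ/N`, `β = 0.95 + σ²/N` — end-biased
  scission; `β > 0.95` always, comfortably above the β > 0.5 validity
  bound.

Two conventions bind `x` (the support index) because the source
formulation leaves it open: `source_class` (`x = i`; default — the
admissible jumps from class `i` number `N − i`) and `jump_distance`
(`x = j − i`, giving one shared jump profile).  Both are regression-tested;
neither reproduces the published 11×11 worked-example matrix, whose
generating computation is not reproducible from the stated rules (its
corner entry even matches the *Weibull* constant); that matrix ships as a
verbatim fixture for internal-consistency checks only.

### Normalization

Diagonals are `1 − Σ` (column off-diagonals).  The printed corner rule
(`P_00 = 1/(N+1)` Gauss, `3.5/(N+1)` Weibull) leaves column 0
unnormalized; `strict_paper` mode keeps it and records the defect,
`conservative` mode (default for simulation) recomputes `P_00` so every
column is stochastic and mass is conserved.

A column whose off-diagonal density sum exceeds 1 is rejected with a
`NormalizationError` naming the column: probabilities are per-step
quantities and the step (or rate scale) is then too large.  This is not a
corner case — the Weibull shape map grows like `β ≈ 0.95 + N/12`, so the
raw density at integer jumps sums above 1 from `N = 23` upward
(`source_class`; `N = 39` for `jump_distance`).  Large-`N` Weibull chains
are therefore only simulable with a rate scale below 1: either the
acid/temperature modulation factors `g·h` (≈ 0.24 at the bundled 100-CB
scenario conditions), applied during construction exactly as the modulated
branch formulas do, or an explicit `breaking_scale` (used by the
calibration benchmark).

### Mass weighting

The mass-unit matrix re-proportions a column's off-diagonals by
destination molar mass, `P^m_ji ∝ M_j α_ji`.  Taken literally the printed
ratio normalizes each column's off-diagonals to 1 — which would force
every chain to cleave each step — so the implementation rescales the
mass-weighted proportions to the column's breaking probability `p_i`,
preserving the survival probability of the probability-unit matrix while
honoring the mass-weighted split.

### Modulation

`g = (c_a/c_a,ref)^n`, `h = exp[(E/R)(1/T − 1/T_ref)]`, with `E_AG` on the
glucose→HMF entry `(N, N−1)` and `E_Am` elsewhere.  The exponent sign is
kept **as printed**, which makes rates *decrease* with temperature for
positive activation energy — the opposite of the Arrhenius form used by
the deterministic rate constants.  A switch
`arrhenius_sign ∈ {as_printed, physical}` flips it; `as_printed` is the
default so the bundled scenarios reproduce the source behaviour.
Defaults `E_Am = 170 kJ/mol` (dilute-acid cellulose hydrolysis,
literature range ≈ 170–180) and `E_AG = 130 kJ/mol` (glucose dehydration,
≈ 120–140) are package choices; the source's own parameter table is in
supplementary material and not reproduced here.

### Dynamics

Discrete path: `ω(τ_{n+1}) = P ω(τ_n)` from `ω(0) = e_0`.  Continuous
path: `dω_i/dτ = Σ_h α_ih ω_h − ω_i Σ_j α_ji` with `α = P_offdiag/Δτ`
(the conversion the dimensional form of the balance requires), integrated
with fixed-step classical RK4 — deterministic and reproducible; the two
paths agree to first order in `Δτ` and the convergence ratio under step
halving is asserted in the tests.  Concentrations are `c_i = ω_i·c_C0`
(g/L).  Unabsorbed mass decays eventually at rate
`max_i P_ii` (the subdominant eigenvalue of the triangular matrix); note a
single-step geometric bound cannot hold since absorption takes several
cleavage generations.

### Deterministic reference

`C →k1→ G →k2→ HMF` with `c_C = c_C0 e^{−k1τ}` and
`c_G = c_C0 k1/(k2 − k1)(e^{−k1τ} − e^{−k2τ})` — the standard consecutive
solution; the source's printed denominator `(k1 − k2)` yields negative
concentrations for `k1 > k2` and is treated as an erratum (the corrected
form is validated against independent stiff integration).  The equal-rate
limit `c_C0 k1 τ e^{−k1τ}` engages below a relative rate difference of
1e−10.  Rate constants follow
`k = k0 (c_a/c_a,ref)^n exp(−EA/RT)`; enzymatic first-order constants use
the Langmuir form `kmax·c_E1/(K_L + c_E1)` (the Michaelis–Menten treatment
of the cellobiase step is out of scope).

### Agreement metrics and calibration benchmark

RMSE per species, and CV = RMSE / mean of the *deterministic* (reference)
trajectory over the compared horizon — the source never defines its CV
normalization, so the choice is recorded in the report metadata.
Trajectories on different grids are restricted to the coarser grid
(optional linear interpolation behind a flag).  Default class↔species
mapping: class `N−1` ↔ G, class `N` ↔ HMF.

The calibration benchmark ties the two models together with one physical
constant: every breaking probability is scaled so the intact-chain class
decays exactly as `e^{−k1τ}` (chosen `k1 = 0.05 s⁻¹`, a dilute-acid rate
at ~200 °C; `Δτ = 10 s`, `N = 100`, `c_C0 = 100 g/L`, 600 steps), and the
deterministic scheme shares that `k1` while `k2` is fitted by least
squares to the chain's glucose class.  The residual glucose RMSE is
**structural**: the chain produces glucose only after ~log₂(PD) mid-chain
cleavage generations (Gauss) or ~PD/2 end-chipping events (Weibull, whose
scission mean is ≈ λ ≈ 1.9 classes), while the one-step scheme produces it
from the first instant; measured mismatches are ≈ 16 % (Gauss) and ≈ 33 %
(Weibull) of the glucose peak under these conditions.  The benchmark
reports this honestly rather than absorbing it into extra fitted
parameters.

## What the scenarios emulate — and what they do not

The bundled scenarios are *hypothetical* chains (10 and 100 CB units) with
idealized uniform ladders, single-species feed, binary cleavage, no
recombination and no heterogeneous effects (crystallinity, accessibility,
mass transfer, enzyme adsorption dynamics).  Passing tests therefore
demonstrate internal correctness of the stochastic machinery and its
stated relationships to the deterministic scheme — not predictive accuracy
for real biomass.

## Numerical choices

* Column stochasticity asserted to 1e−12; state-sum conservation to 1e−9
  over 10⁴ steps.
* Degenerate Gauss (`σ = 0`, only at `x = N`) is an explicit point mass at
  the mean, not an epsilon-widened density.
* Problem sizes in tests and the acceptance script (N ≤ 100, ≤ 10⁴ steps,
  600-step benchmarks) keep the full suite in the low tens of seconds;
  they are the sizes the worked examples themselves use.
* CSV serialization uses 17 significant digits (exact float round-trip);
  human-readable views round to 3 decimals like the published matrix.
* The pipeline contains no randomness; any future Monte-Carlo extension
  must take an explicit seed.

## Known limitations

* The published worked-example matrix is not reproducible from the stated
  construction rules (documented above); only internal-consistency checks
  against it are possible.
* Raw (unscaled) Weibull matrices do not exist for `N ≥ 23`
  (`source_class`) — a defect of the printed shape map, handled by
  explicit errors plus scaled construction.
* Single-descendant bookkeeping: the complement fragment of each cleavage
  is not deposited in its own class, so fragment-size distributions are
  those of the tracked-descendant process, and chain-end (Weibull)
  scission shows no immediate small-fragment production.
* The as-printed temperature factor is anti-Arrhenius; use
  `arrhenius_sign="physical"` for conventional behaviour.
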