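# Methods

## Model and assumptions

A classical two-arm randomized test-treatment trial randomizes patients 1:1
between diagnostic tests A and B. Per patient the generative chain is

* disease status D ~ Bernoulli(π), ideally verified by a reference standard;
* test result R | D from the arm's sensitivity/specificity
  (Se = P(R=+|D=+), Sp = P(R=−|D=−));
* management M = m(R) with the fixed rule m(+) = I, m(−) = II;
* outcome Y ~ Bernoulli(μ_MD) for the binary endpoint, or a continuous
  response with cell mean μ_MD and common SD.

The subgroup outcomes μ_md are **shared between arms** (no test-by-treatment
interaction): a correct or incorrect management decision has the same effect
regardless of which test produced it. The general formulation would allow
test-specific μ; we implement only the shared form, since every scenario of
interest uses it and it keeps the arm difference interpretable as a pure
accuracy effect. Under this model the expected arm outcome
θ_t is linear in π, and the arm difference can cross zero at some prevalence
when the tests trade sensitivity against specificity.

The effect of interest is Δ = θ_A − θ_B, tested two-sided with the unpooled
Wald z-statistic for two independent proportions; rejection is strict
(p < α). Degenerate replications with zero variance in both arms never
reject.

## Sample sizes

* Binary endpoint: the standard normal-approximation formula for two
  proportions with the pooled rate θ̄ under H₀ and the unpooled variances
  under H₁. Per-arm values are rounded up (ceiling), totals are therefore
  even.
* Continuous endpoint: the two-independent-means formula. The default is
  the iterative t-quantile refinement (smallest n with
  n ≥ 2σ²(t_{1−α/2,2n−2} + t_{1−β,2n−2})²/Δ², initialized at the normal
  solution); the plain normal version is available. The iterative method
  agrees with statsmodels' noncentral-t power solver on every case in the
  test suite.
* Planning-stage sizes evaluate the model at the assumed prevalence
  (`planned_size`), the "true necessary" size at the true prevalence
  (`required_size`). For continuous endpoints the planning call accepts an
  explicit Δ override, because protocols typically plan on a rounded
  clinically-stated difference (0.2 TBscore points in the worked example —
  only the rounded value reproduces the planned total of 3,142) while the
  model-implied effect (0.20925) remains the internal reference.

## Blinded recalculation

One interim look, no early stopping, no α adjustment. The internal pilot
size is N₁ = ceil(N₀·f) rounded **up to the next even integer** so both arms
fill under 1:1 allocation; worked arithmetic that keeps an odd N₁ differs by
at most one patient. The prevalence is re-estimated either as the binomial
MLE n/N₁ from reference-standard positives or by inverting the overall
positive rate P⁺ (the sum of the two per-test positive probabilities; the
observed pooled positive fraction estimates P⁺/2 under 1:1 allocation). The
inversion enforces the attainable range
[(1−Sp_A)+(1−Sp_B), Se_A+Se_B] — tighter than the formal constraint
0 ≤ P⁺ ≤ Se_A+Se_B — and fails loudly when the summed Youden index is zero.

The recalculated N* substitutes π̂ into the sample-size formula while
keeping the accuracy and outcome parameters at their planning
(alternative-hypothesis) values; the final size is max(N₁, N*), so pilot
patients are never discarded. If the effect at π̂ is (numerically) zero the
required size is infinite; instead of erroring, N* is capped at a
configurable n_max (default 10·N₀) and flagged, so replication loops never
abort. All validation is strict-rejecting: out-of-range probabilities raise
errors rather than being clamped, because silent clamping hides mistakes in
grid configuration files.

Blindness is enforced structurally: the interim snapshot type carries only
the pilot size, the pooled count of reference-standard positives and the
pooled positive fraction — outcomes and arm labels cannot reach the
recalculation.

## Null scenarios

A scenario's "null twin" keeps every parameter but generates data with test
A's accuracy in both arms, which is the minimal change forcing θ_A = θ_B
while preserving the outcome structure. Planning and recalculation still
use the alternative-hypothesis accuracies (a trial is sized for the effect
it hopes to detect and then evaluated under no effect); a literal
substitution everywhere would make the planned size infinite.

## Simulation engines and reproducibility

Two generators produce the same law: a per-patient generator (used for
fixtures and oracle tests) and an aggregated engine drawing binomial counts
per (arm × disease × result) cell, vectorized across replications — the
workhorse that makes the full factorial study (1,620 scenarios ×
adaptive/fixed × alternative/null) run in minutes on one CPU. Their
equivalence is checked by chi-square homogeneity of cell counts in the test
suite.

Randomness: one root seed; the grid runner derives one independent
`SeedSequence` substream per (scenario, hypothesis, design), so identical
configuration and seed reproduce every output bit-for-bit. The scalar
replication path uses its own generator; the two paths agree statistically,
not bit-wise. Adaptive and fixed designs use independent streams (no common
random numbers).

## The factorial grid

Defaults: π_true ∈ {0.2, 0.4}; π_assumed ∈ {0.1, …, 0.5}; Se_A ∈
{0.8, 0.9, 0.95}; Sp_A ∈ {0.8, 0.9, 0.95}; Se_B ∈ {0.6, 0.7, 0.8}; Sp_B ∈
{0.6, 0.75, 0.9}; μ_I+ ∈ {0.05, 0.1}; fixed μ_II+ = 0.25, μ_I− = 0.2,
μ_II− = 0.05; f = 0.5; α = 0.05; power 0.80 — a 2·5·3⁴·2 = 1,620-scenario
grid. The values exercised by the worked scenarios and the fixed μ values
are fixed by design; the remaining list entries are **declared assumptions**,
configurable in `GridConfig` or a grid YAML file.

Grid-level caveats under these defaults:

* 36 scenarios have an exactly zero effect at the assumed or true prevalence
  (no finite sample size exists). They are skipped with a logged count and
  excluded from summaries.
* some accuracy combinations make the effect at the assumed prevalence much
  smaller than at the true one; the planned N₀ — and hence the pilot N₁ —
  then exceeds the true necessary size, and no blinded recalculation can
  remove patients already recruited. Such scenarios are intrinsically
  overpowered (about 8% of the kept grid); a further handful hit the N*
  cap in the opposite direction and stay underpowered. The *median* power
  across the grid is insensitive to these tails; the claim "every scenario
  within Monte-Carlo noise of 0.80" holds only for grids whose assumed
  effects stay comparable to the true ones.

## Problem sizes used

The acceptance script and test suite run the single-scenario analyses at
10,000 replications and the full grid at 1,000 replications per scenario
(Monte-Carlo SE of a power estimate ≈ 0.013), with the null-twin type-I
check at 10,000 replications (SE ≈ 0.002). These sizes were chosen so the
whole study reproduces in minutes at desk scale; all replication counts are
parameters, and the full 10,000-replication grid is a single `GridConfig`
call away.

## What the synthetic data do and do not show

The generator emulates exactly the idealized trial model: Bernoulli disease
status with constant prevalence, conditionally independent test errors with
known constant accuracies, deterministic management, immediate binary
outcomes, no dropout, no drift over recruitment, no covariates and no
test-by-treatment interaction. Passing tests therefore demonstrate the
*internal* consistency and calibration of the design machinery, not
robustness to violated assumptions in real trials (misspecified accuracies,
delayed outcomes, unverified disease status, non-compliance). The
recalculation's validity also leans on every parameter except the prevalence
being known exactly — its stated prerequisite.

## Known limitations

* Binary-endpoint simulation only; continuous endpoints are covered by the
  deterministic planning formulas.
* Two tests, binary results, the fixed management rule and 1:1 allocation.
* No multiple interim looks, group-sequential boundaries, or unblinded
  effect-based re-estimation.
* The positive-rate prevalence estimator is implemented and tested as an
  inversion identity; its Monte-Carlo behaviour inside the adaptive design
  is not part of the simulation study.
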