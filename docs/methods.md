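# Methods

## The design family

A trial evaluates K candidate interventions with a binary success
outcome. Each participant receives a subset of interventions according to
the design:

| kind | per-patient allocation |
|---|---|
| `distributive` | exactly k of K, uniformly at random among feasible combinations |
| `capped_factorial` | any subset of size ≤ k |
| `full_factorial` | independent coin per intervention (ignores the per-patient limit) |
| `controlled_distributive` | distributive, plus an intervention-free arm with probability c |
| `parallel` | one intervention, plus a shared control arm; all arms equally sized |
| `separate` | K independent two-arm trials |

The distributive design is the object of interest; the others are
comparators. The full factorial is an idealized benchmark that violates
the per-patient limit; the parallel-arm design is the conventional
alternative.

## Exact allocation tables

Enumerating all C(K, k) arms is unnecessary when most interventions are
exchangeable. An intervention is *interesting* when it has a presumed
non-null effect and/or an unbalanced allocation probability p_i ≠ 0.5;
detection is automatic from the effect specification, overridable by the
user. For the L interesting interventions, all 2^L indicator combinations
X_I are listed (first index fastest-varying, for deterministic output)
with

* p′(X_I) = Π_i [X_i p_i + (1 − X_i)(1 − p_i)], the partial-draw
  probability;
* p″(X_I), the probability that the K − L uninteresting interventions
  complete the arm to a feasible total: P(exactly k − l) for exact-k
  designs, P(≤ k − l) for the capped factorial, and 1 for the full
  factorial, with the convention C(Y, y) = 0 outside 0 ≤ y ≤ Y zeroing
  infeasible rows;
* p(X_I) = p′p″ / Σ p′p″.

The count distribution behind p″ is built by convolving one Bernoulli per
uninteresting intervention, so arbitrary (unbalanced) allocation ratios
are supported exactly; with balanced interventions it reduces to
Binomial(K − L, ½), computed exactly in binary floating point. For the
controlled distributive design the normalized rows are scaled by (1 − c)
and an explicit control row with probability c is appended — of the two
possible readings of "adjusting the other terms", this scale-after-
normalizing contract is the one implemented, and c = 0 reduces exactly to
the distributive design. Tables are validated in the test suite against
brute-force enumeration of all arms for K ≤ 10 (tolerance 1e−10) and sum
to 1 within 1e−12. Probabilities use ordinary doubles; K is capped at 64,
far above 0.5^K underflow territory.

## Outcomes

Effects are an explicit prioritized rule list over interesting
interventions: baseline success (0.5 throughout the shipped scenarios)
plus (combination → success probability) pairs. The largest matching
combination wins; equal-size matches with conflicting values raise an
error rather than resolving silently — ambiguity is treated as a
specification bug. Uninteresting interventions have structurally zero
effect (rules may not reference them). Logit-scale additivity is provided
as a helper: two standalone-70% interventions combine to
expit(2 logit(0.7)) ≈ 0.8448276.

Marginal receiver/non-receiver success rates (the p_I, p_C of the closed
form) are probability-weighted averages over table rows. For an
uninteresting intervention the per-row weight is the completion-draw
inclusion probability (k − l)/(K − L), which reproduces the pooled-
analysis bias: receivers of a null intervention are *less* likely to also
carry the effective one, giving a small contrast in the direction of
harm.

## Simulation

Patients are assigned to combinatorial arms by one multinomial draw over
the table (distributionally identical to per-patient categorical draws,
and faster), the design matrix is completed — a uniform random subset of
k − l uninteresting interventions per patient for exact-k designs,
independent coins for the full factorial — and outcomes are Bernoulli at
each arm's success probability. Every non-control patient in a
distributive trial carries exactly k interventions (hard assertion). The
capped factorial has no completion algorithm (a two-stage
count-then-identity draw would be needed) and refuses to simulate; its
exact table and closed-form sizes are fully supported. Per-patient
completion draws require balanced uninteresting interventions; the
conditional weighted draw for unbalanced ones is out of scope (the exact
table math still covers them).

Inside power loops, trials are drawn directly at the detailed-arm level
(multinomial counts, binomial successes) whenever the full expansion over
all K interventions is small enough; regression analyses operate on the
binomially aggregated data either way, which leaves the maximum
likelihood fit unchanged while keeping fits fast at N up to 30,000.

## Analysis

Two tests are offered per intervention, both at the Bonferroni-adjusted
threshold α/K (the divisor is the number of main-effect hypotheses,
never the number of interaction terms; β is never adjusted):

* pooled difference of proportions (receivers vs non-receivers,
  pooled-variance z-test; degenerate variance yields p = 1);
* the Wald test of the main-effect coefficient in a logistic regression
  with all K allocation indicators, optionally adjusted by two-way
  product terms: always-retained pre-specified terms, a raw
  significance-gated term (gate threshold 0.05 or 0.15), or backward
  elimination (threshold 0.05 or 0.25) starting from all pairs involving
  the tested intervention or from all C(K, 2) pairs, removing the
  worst-p term one refit at a time.

Exact-k allocation makes the intercept-plus-K-mains model structurally
aliased (the indicator columns sum to k; the pairwise products to
C(k, 2)). Later dependent columns are dropped deterministically
(earliest-first maximal independent set via QR), the same resolution R's
`glm` applies when reporting NA coefficients; aliased terms are flagged
and untestable (p = 1). Non-convergence yields p = 1 for all of the
model's tests, and a term with standard error above 100 on the logit
scale (quasi-separation, as in 99%-synergy scenarios) yields p = 1 for
that term — conservative non-discovery in every case, flagged in the
results, never silent. Wald (not likelihood-ratio) statistics are used
throughout. Fits go through statsmodels' binomial GLM; agreement with
R's `glm` is checked in the test suite to 1e−6.

FWER is the proportion of simulated trials with at least one false
rejection of a truly-null intervention, reported with a Jeffreys
Beta(x + ½, n − x + ½) interval.

## Sample size

**Closed form** (single effective intervention, pooled analysis): the
standard unbalanced two-proportion formula with pooled variance under the
null,

n_I = (z_α √((r+1) p̄(1−p̄)) + z_β √(r p_I(1−p_I) + p_C(1−p_C)))² / (r (p_I − p_C)²),

p̄ = (p_I + r p_C)/(r+1), N = n_I + r n_I (both parts ceiled), with r and
p_I, p_C read off the design's allocation table. A variant placing both
variances under one radical in the z_β term exists behind
`as_printed=True` for auditing; the default reproduces textbook values
(124 per group at 0.7 vs 0.5, r = 1, two-sided 5%, 90% power; 220 at
α/20). z-quantiles are two-sided by default (1 − α′/2).

**Adaptive search**: discovery probability is modeled as
p_d = Φ(z_{1−β} + b(X − X₀)) with X = √N — the functional form implied by
closed-form sample-size formulas N = (z_{1−α/2} + z_{1−β})²/effect². The
schedule: two pseudo-observations anchor the fit (failure at N = 1,
success at N = 10⁶); 48 trials log-spaced on [50, 10,000] seed it
(re-drawn, at most 20 times, if all land on one side); then batches of
max(50, 10% of history) are spread uniformly over X̂₀ ± min(SE(X̂₀), 10)
— both on the √N scale — with a refit after each batch, until at least
`min_sims` (default 5000) trials have run. The fit is a probit GLM with
offset z_{1−β}; X₀ = −c₀/c₁ with a delta-method standard error,
equivalent by ML invariance to the observed-information SE in the
(X₀, b) parameterization; a constrained (b > 0) direct ML fallback
handles degenerate histories. The robust variant — the default, replacing
manual re-runs of visually diagnosed outliers — requires b > 0 and refits
the final estimate without the anchors and the initial batch. The result
is N = ⌈X̂₀²⌉.

Calibration is verified two ways in the tests: against the analytic
two-proportion power curve (recovered N within 3% at 5000 oracle draws),
and end-to-end — sizes returned for single-effective-intervention
scenarios, re-checked with fresh simulated trials, give observed power
consistent with the 90% target (the expected spread of such a two-stage
check at 5400 + 5000 simulations is √(0.09/5400 + 0.09/5000) ≈ 0.59%).

## Scenario presets and problem sizes

The preset catalogue encodes the canonical scenario groups (baseline 50%;
one or two effective interventions at 70%; combinations additive on the
logit scale, synergistic at 99%, non-additive at 70%, or weaker at 60%;
k from 2 to 8 among K from 4 to 20; control arms from 0 to 80%) at three
scales: `smoke` (200 simulations, coarse grids — for CI and exploration),
`desk` (1000), `full` (5000, complete grids — Monte-Carlo SE ≈ 0.42% at 90%
power). The shipped test suite and the acceptance script run at reduced
simulation counts (300–2000 per estimate) with correspondingly wider
Monte-Carlo bands; the estimators themselves are scale-invariant.

## What the generator does and does not emulate

Simulated trials are idealized: fixed N, no dropout, missingness,
non-compliance or sequential enrolment; binary outcomes only; effects
constant over time and patients; uninteresting interventions exactly
null. Passing tests therefore demonstrate the statistical machinery —
allocation combinatorics, error control, power calibration — under the
stated generating model, not robustness to real-data pathologies such as
covariate drift or informative missingness.

## Known limitations

* No forbidden/enriched combinations and no dose levels within an
  intervention (the design space is subsets of size k only).
* Capped-factorial designs cannot be simulated patient-wise (exact table
  and closed form only).
* Per-patient completion draws require balanced uninteresting
  interventions.
* The gated strategy's interaction gate is raw (no multiplicity
  accounting), by construction.
* Estimation-focused inference (confidence intervals, Firth or Bayesian
  fits, exact tests) is out of scope; the engine tests hypotheses.
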