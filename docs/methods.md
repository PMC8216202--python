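# Methods

## The measurement problem

In two-choice discrimination between a feature-present stimulus (S1) and a
feature-absent one (S2), metacognitive sensitivity — how well trial-by-trial
confidence tracks accuracy — can differ between the two *responses*. The
package quantifies this with response-conditional type-2 ROC areas and tests
four directional group-level hypotheses on participant-level difference
scores: mean confidence (H1), auROC (H2), auROC beyond the equal-variance SDT
expectation (H3), each predicted higher for S1 responses, and mean log RT
(H4), predicted lower for S1 responses.

## Type-2 ROC construction

For each response, thresholds sweep the distinct observed confidence values
in descending order; each threshold contributes the point
(P(conf ≥ t | incorrect), P(conf ≥ t | correct)), with (0, 0) and (1, 1)
anchors, and the area is the trapezoidal integral. Taking thresholds at
distinct values makes tied ratings move together, so the area equals the
tie-corrected Mann-Whitney statistic exactly; the test suite asserts this
equivalence against a brute-force pairwise oracle at 10⁻¹² on a thousand
random instances. The area is therefore invariant under strictly monotone
rescalings of the confidence axis, and whether thresholds are defined with ≥
or > is immaterial. The 20-bin confidence summary (equal-width bins spanning
each participant's dynamic range) is exported for plotting only and never
enters an area.

A curve requires at least one correct and one incorrect trial per response;
the pre-registered exclusion rule (at least two errors of each response type)
guarantees this with margin for every included participant.

## Equal-variance SDT control (H3)

A criterion displaced from the midpoint of the evidence distributions makes
the two response-conditional areas differ even when confidence is generated
by a perfectly symmetric equal-variance observer. The control computes the
ΔAUC such an observer would produce, matched to the participant on three
things: sensitivity, response bias, and the empirical distribution of
confidence in incorrect trials.

Fitting uses the standard estimators d′ = z(HR) − z(FAR),
c = −½(z(HR) + z(FAR)). Note the convention: this `criterion_c` is measured
from the midpoint of the two distributions; the absolute cutoff on the
evidence axis (S2 distribution centred at zero) is `criterion_abs` =
c + d′/2. Extreme rates are corrected by the 1/(2N) rule by default
(`correction="loglinear"` applies the log-linear +0.5/+1 alternative).

For an equal-variance observer whose confidence is any monotone function of
the distance between the decision variable x and the cutoff χ, the type-2
hit rate at type-2 false-alarm proportion p has a closed form. For S1
responses (x > χ; correct trials are S1 stimuli, errors S2 stimuli): solve
Φ̄(θ) = p·Φ̄(χ) for θ and return Φ̄(θ − d′)/Φ̄(χ − d′), where Φ̄ is the
standard normal survival function. S2 responses mirror the construction
below the cutoff. The quantile-function solution is exact (no root-finding
tolerance). Each participant's model curve is evaluated at their empirical
cumulative error-confidence proportions and integrated by the trapezoidal
rule, mirroring the empirical construction; the H3 statistic is
ΔAUC − ΔAUC_model.

Validation: on ideal equal-variance observers with a strongly biased
criterion (10⁵ trials each), the empirical ΔAUC is clearly nonzero while the
mean of ΔAUC − ΔAUC_model stays within Monte-Carlo error of zero; on
unequal-variance observers (σ₁ = 1.5) the residual asymmetry is large and
positive. Both checks run in the acceptance suite.

## Inference

Each hypothesis is a one-sample, one-tailed t-test on participant-level
differences (α = 0.05; Cohen's d = mean/SD), plus a JZS Bayes factor: a
Cauchy(0, rscale) prior on the standardized effect δ, with
BF₁₀ = ∫ f(t | ν, δ√n_eff) π(δ) dδ / f(t | ν, 0), where f is the noncentral-t
density of the observed statistic. The substitution δ = rscale·tan θ maps the
prior to a uniform density on (−π/2, π/2); scalar calls use adaptive
quadrature (relative error 10⁻⁸, non-convergence raises with diagnostics) and
simulations use fixed 301-node Gauss–Legendre quadrature, which the tests tie
to the adaptive result at 10⁻⁶ relative error and to two independent oracles
(a 10⁶-point Riemann sum over the prior, and pingouin's closed-form JZS
implementation).

rscale defaults to 0.65. Because the confirmatory hypotheses are directional,
the battery defaults to the directional prior (all mass on the predicted
sign, implemented as the positive half-Cauchy applied to the appropriately
signed t); the symmetric two-sided prior is available via
`bf_alternative="two_sided"`, and every report records which was used. No
multiplicity correction is applied: the four hypotheses are separate
pre-registered confirmatory tests.

Degenerate inputs are rejected rather than patched: fewer than 3
participants, zero variance in the difference scores, or a missing response
class all raise.

## Design analysis

`power_one_tailed(n, d, alpha)` is the exact noncentral-t power
P(T_{n−1, d√n} > t_crit). At n = 106, d = 0.32, α = 0.05 it returns 0.948,
i.e. 95% to two decimals.

`bf_outcome_simulation` draws, per repetition, a true standardized effect
(zero, or Cauchy(0, 0.65)), simulates raw data at the planned sample size,
and computes the JZS Bayes factor, tallying the percentages of repetitions
with BF01 > 1, BF01 > 3, BF10 > 1, BF10 > 3 (with the worst-case binomial
Monte-Carlo standard error, 0.5 points at the default 10,000 repetitions).
Following the Schönbrodt-style Bayes-factor design analysis it simulates the
**two-sample** design by default — two groups of n = 106, pooled-variance t,
effective sample size n/2 and 2n − 2 degrees of freedom — with the two-sided
JZS prior; a paired/one-sample mode (`design="paired"`) is provided. Under
these defaults the simulated outcome percentages are, at Monte-Carlo
precision: ≈95% null support and ≈79% BF01 > 3 under a true null, and ≈76%
alternative support, ≈70% BF10 > 3, ≈15% BF01 > 3 under Cauchy effects —
the values the acceptance script recomputes.

## Synthetic observers

The generator reproduces the experiment's trial structure: 96 trials in 6
blocks, SOA staircased 1-up-2-down with multiplicative step 0.9 from 30 ms
(two consecutive correct responses shrink the SOA, any error grows it; the
procedure converges on √0.5 ≈ 70.7% accuracy, verified to ±2 points over a
long stationary run). SOA maps to sensitivity through a saturating
hyperbola d′(soa) = dprime_max·soa/(soa + soa_half_point_ms) — a one-knob
psychometric link chosen for interpretability (half-point in ms). The
staircase runs from trial 1; block 1 is removed by the downstream filter,
as in the experiment.

Evidence is unequal-variance SDT: x ~ Normal(d′, σ₁) for S1, Normal(0, 1)
for S2; respond S1 iff x > criterion (absolute cutoff, default 0.6), flipped
with lapse probability 0.02 so the exclusion rules have something to catch.
Confidence is 2·logistic(|x − c| + ε) − 1 clipped to [0, 1] with metacognitive
noise ε ~ Normal(0, 0.1) — a monotone squashing of distance-to-criterion onto
the unit scale. RT is lognormal with log RT ~ Normal(log(900 ms) −
0.8·confidence, 0.35), encoding the inverse confidence–RT relation that
motivates H4.

Cohorts draw per-participant parameters from truncated normal population
distributions, each participant on an independent stream derived from the
master seed (reproducible, and stable under cohort growth). The defaults are
calibrated once to the pilot-scale regime of the study design: with
σ₁ ~ Normal(1.15, 0.1) truncated at 1, 200 simulated participants give a
participant-level ΔAUC effect size d ≈ 0.69 (H3 ≈ 0.67, H1 ≈ 0.59,
H4 ≈ −0.37) with ≈4% of participants excluded. Setting
`sigma_s1_mean = 1, sigma_s1_sd = 0` (`equal_variance_population()`) yields a
null cohort whose ΔAUC distribution is symmetric about zero.

What the generator does *not* emulate: stimulus content and masking dynamics
(SOA is the single effective-visibility variable; the 50 ms stimulus duration
and 100 ms mask are not modelled separately), sequential effects, learning or
fatigue drifts, response-key effects, the 2 s minimum confidence-rating
interval, and any non-SDT contamination of confidence (e.g. attention
lapses that affect confidence but not choice). Passing tests on synthetic
cohorts therefore validate the *pipeline's* correctness and the internal
consistency of the SDT reasoning — not the empirical truth of the
unequal-variance account for human observers.

## Numerical and design choices

- Natural log for RTs; the base only rescales both sides of H4 jointly.
- Accuracy and error-count exclusions are computed on the analyzed
  (post-filter) trials, which are the trials that feed the ROCs; the
  RT-violation proportion uses all trials, as its wording implies.
- ROC areas always come from unbinned ratings.
- Trial filtering is idempotent and order-preserving; exclusion decisions are
  invariant to trial order.
- JZS quadrature failures (pathological inputs) raise rather than return a
  value; far-tail noncentral-t underflow inside the integrand is treated as
  zero density, and a central-t density underflow at astronomically large |t|
  returns BF₁₀ = ∞ rather than NaN.
- Problem sizes in the validation suite (10⁴ design repetitions, 10⁵-trial
  control observers, 10⁷-trial Monte-Carlo oracle, 5·10⁴-trial staircase
  runs) were chosen so Monte-Carlo error sits comfortably below each
  assertion's tolerance.

## Known limitations

- The equal-variance control conditions on estimated d′ and c as if they
  were known; at 80 analyzed trials their sampling error propagates into the
  H3 statistic (it is unbiased under the null in our checks, but noisy).
- The matched model assumes confidence is monotone in distance-to-criterion
  for the ideal observer; metacognitive noise in the *generator* is absorbed
  empirically by H3's subtraction logic only to first order.
- `bin_confidence` collapses to a single degenerate bin (with a warning) when
  a participant uses one confidence value exclusively.
- The CLI exposes the six stimulus-pair experiments only as labels; they
  differ in no other way inside the simulator.
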