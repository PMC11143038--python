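# Methods

`driftsem` implements an analysis chain for two-choice reaction-time (RT)
batteries: trial screening, drift–diffusion parameter estimation with the
Kolmogorov–Smirnov (KS) criterion, psychometric scoring, and a ladder of
confirmatory latent-variable models that asks whether a common
executive-function (EF) factor carries any variance beyond task-general
speed of information uptake. A synthetic battery generator with known
latent ground truth makes every stage verifiable by recovery experiments.

## Diffusion model

A decision is modelled as a Wiener process with unit diffusion
coefficient accumulating evidence between absorbing boundaries a distance
`a` apart, starting at relative position `zr` (fixed at 0.5, i.e. midway:
unbiased), with drift `v` toward the correct (upper) boundary. The
observed RT adds a non-decision time `t0` that varies uniformly across
trials over a range `st0` (support `[t0 − st0/2, t0 + st0/2]`). All other
inter-trial variabilities are fixed to zero, and `zr` is never estimated.
With unit diffusion, drift rates for typical speeded tasks land in the
range 1.5–6.5.

Closed forms used throughout: the probability of a correct response is
`(1 − e^{−2 v zr a}) / (1 − e^{−2 v a})`, which reduces to
`1/(1 + e^{−a v})` for `zr = 0.5`; the zero-drift mean decision time is
`z(a − z)` = `a²/4` at the unbiased start.

### First-passage numerics

Densities use the two standard series representations of the Wiener
first-passage-time density (an image expansion accurate at small times
and a sine-series spectral expansion accurate at large times), selected
per evaluation point by comparing the number of terms each needs for an
absolute tolerance of 1e−6. CDFs integrate the spectral series termwise;
below normalised time `w = t/a² ≈ 0.05` (numpy reference path) the
density is integrated with a 64-node Gauss–Legendre rule instead, because
the integrated sine series converges slowly there.

The non-decision-time range enters by convolution with the uniform
window. The reference path averages the CDF over an 11-node
Gauss–Legendre rule on the window. The compiled kernel used inside the
estimation loop instead folds the convolution into the series exactly:
averaging `e^{−λ_k t}` over the window multiplies each coefficient by
`2 sinh(λ_k st0/2)/(λ_k st0)`, handled in log space because the factor
overflows for deep terms. The two paths agree to ≤ 1e−10 and are pinned
against each other in the test suite. Below `w = 0.005` the accumulated
mass is smaller than ~1e−10 (the nearest image must travel half a
boundary width) and is treated as zero.

### Simulation

Two simulators exist with different purposes:

* `simulate_trials` — Euler–Maruyama path simulation (default
  `dt = 1e−4` s). Discrete monitoring lets paths overshoot the
  boundaries, biasing absorption statistics outward by ≈ `0.5826·√dt`
  per boundary; both boundaries are pulled inward by that continuity
  correction so the simulated process matches the continuous model. It
  serves as the *independent* oracle for the analytic densities (it never
  touches the series code).
* `sample_first_passage` — inverse-CDF sampling on a dense grid of the
  analytic CDF. Fast and exact up to interpolation on a 2048-point grid;
  used by the synthetic-data generator.

### KS estimation

Correct-response RTs are mapped to positive values and error RTs to
negative values, forming one joint distribution whose total mass splits
between the boundaries. Estimation minimises the supremum distance
between the empirical and model CDF of this signed variable (the model
CDF is continuous and monotone, so evaluating at the data jump points is
exact). Multi-condition tables share `a`, `t0`, `st0` across conditions
with condition-specific drift; the objective is the trial-weighted mean
of per-condition KS statistics.

Starting values are moment-based (EZ-style: drift and boundary from
accuracy and RT variance, non-decision time from the mean RT), with an
edge-corrected accuracy `(x+0.5)/(n+1)`. The default optimiser is
Nelder–Mead with jittered restarts; `method="global"` runs seeded
differential evolution with a simplex polish. Bounds:
`a ∈ (0.1, 5)`, `v ∈ (−10, 10)`, `st0 ∈ (0, 2 t0)`, and the support
floor `t0 − st0/2` must stay below the smallest RT. The floor constraint
(rather than `t0 < min RT`) matters: with a wide non-decision window the
true `t0` legitimately exceeds the smallest observed RT, and constraining
`t0` itself biases the boundary separation upward.

**A deliberate measurement choice.** On tasks with near-ceiling accuracy
(unit-scaled drifts above ~5) the KS surface has a flat ridge in
(v, a): many parameter pairs imply almost the same signed-RT
distribution when errors are rare. Fully minimising the KS statistic
then *degrades* the between-person ordering of drift estimates — on a
two-choice-like probe (v ≈ 6.25, 100 trials) the squared correlation
with truth falls from ≈ 0.72 at the moment-based start to ≈ 0.42 at the
global minimum, because the optimiser chases sample noise along the
ridge. Battery-level measurement (`fit_battery_ddm`) therefore uses a
capped simplex budget (40 iterations, one start) refining the moment
start: a deliberate bias–variance trade that reproduces the split-half
reliability profile this kind of battery shows in practice (roughly
0.45–0.90, lowest for high-drift tasks). Full minimisation remains the
default of `DiffusionModel.fit`, and recovery studies use
`method="global"`.

Recovery characteristics worth knowing: across a 20-person grid spanning
drifts 1.7–5.5 at 192 trials, globally-optimised estimates correlate
with truth at roughly 0.86–0.91 — the ceiling-accuracy ridge, not
optimiser failure (at the global optimum the fitted KS is below the KS
of the true parameters). Median absolute drift error shrinks with trial
count.

## Preprocessing

Fixed order, single pass, all removals logged:

1. drop trials faster than 150 ms (strictly; exactly 150 ms is kept);
2. per participant × condition, drop trials with `|z(log RT)| > 3`
   (sample SD, computed once — no iteration; groups with < 3 trials or
   zero variance are left alone);
3. per task condition, exclude participants below the exact binomial
   guessing threshold — the smallest correct count `c` with
   `P(Bin(n, 1/alternatives) ≥ c) ≤ α`, `α = 0.05` one-sided — and
   participants whose mean RT or empirical-logit accuracy
   (`logit((x+0.5)/(n+1))`, finite at perfect scores) deviates more than
   3 SD from the sample mean; exclusions apply to the whole task;
4. person-level derived scores beyond 3 SD are set missing (handled
   later by full-information likelihood), not deleted listwise.

Reapplying the pipeline to its own output is detected and refused — the
trims are single-pass by contract. On contaminant-free simulated
batteries the log-z step removes roughly 0.5–1% of trials per condition.

## Scores and reliability

Heterogeneous scores mirror traditional EF scoring: RT difference scores
(demanding − baseline, correct trials only) and demanding-condition mean
RTs for inhibition tasks, arcsine-transformed proportion correct
(`asin√p`, applied at the finest block level available, then averaged —
the transform is convex above p = 0.5, so block-level averaging sits
above the person-level transform) for updating tasks, RT differences for
shifting, mean RT for elementary speed tasks. Homogeneous scores are the
demanding-condition drift rates, plus drift differences
(baseline − demanding, so a larger value again means a larger demand
effect).

Reliability: Spearman–Brown-corrected odd–even split-half correlations
(`2r/(1+r)`; split on trial-index parity within condition, after
preprocessing; drift-based reliabilities refit the diffusion model per
half with the same fixed-parameter policy) for trial-based scores, and
Cronbach's α (`k/(k−1)·(1 − Σ item var / total var)`, listwise-complete)
for item scales. Inadmissible negative split-half values are reported,
never clipped. Difference scores of positively correlated components are
systematically less reliable than either component — the simulation
reproduces this well-known psychometric fact.

## Latent-variable engine

Models are declared as loading/covariance/regression patterns over
observed and latent variables; the implied covariance is
`Σ = Λ(I−B)⁻¹Ψ(I−B)⁻ᵀΛᵀ + Θ`. Means are saturated, so they add no
degrees of freedom; `df = p(p+1)/2 − (free structural parameters)`.
Scale setting: the first loading of each factor is fixed to 1 and the
factor variance estimated.

Estimation maximises the casewise normal log-likelihood grouped by
missingness pattern (FIML), using per-pattern sufficient statistics so
the cost is independent of sample size given the pattern structure. With
complete data the mean profiles out at the sample mean and the method is
exactly normal-theory ML. The optimiser is L-BFGS-B on the unconstrained
parameters; variances are *not* log-transformed, so boundary solutions
surface as small negative estimates (Heywood cases) and are reported as
warnings rather than hidden — fixing a residual variance to zero is an
explicit model constraint, not a clamp. Standard errors come from the
observed information (central-difference Hessian at the optimum).

The saturated log-likelihood (for the χ² statistic) uses the closed form
with complete data and an EM algorithm for the multivariate-normal
mean/covariance under missingness; it is unavailable when there are
fewer persons than variables, in which case χ²-based indices are
reported as undefined rather than fabricated. The CFI baseline is the
independence model with free means and variances, whose FIML solution
factorises into per-variable available-case estimates.

Fit indices: `CFI = 1 − max(χ²−df, 0)/max(χ²_b−df_b, χ²−df, 0)`;
`RMSEA = √(max(χ²−df, 0)/(df(N−1)))` with a 95% confidence interval by
inverting the noncentral-χ² distribution at 2.5/97.5% (the N−1
convention is used throughout, also in the power functions, where it is
required to reproduce standard published power values); `AIC = −2ℓ + 2k`
counting all estimated parameters, with differences ≥ 10 flagged as
substantial in model comparisons (refused across different samples).
Parameter inference uses the two-sided critical-ratio (Wald z) test.

### The model ladder

Nine EF indicators grouped 3/3/3 (inhibition, updating, shifting), three
elementary speed tasks, four working-memory-capacity (WMC) indicators,
four intelligence component scores. The ladder: correlated three-factor
model (df 24); higher-order model (df 24; with first-order residual
variances fixed to 0, df 27 — analytically equivalent to the one-factor
model, and the two fits attain identical log-likelihoods); one-factor
model (df 27), optionally with WMC and intelligence factors (df 115);
speed-regression models in which the common EF factor is regressed on
the speed factor, with the EF disturbance free (df 53) or fixed to zero
(df 54), optionally with the criterion factors (df 166).

Two constraint patterns were genuinely open design points and are
explicit options: (1) the difference-score variant of the three-factor
model constrains the three inhibition loadings to equality (difference
scores share a scale), giving df 26 rather than 24; (2) the criteria
models free one residual covariance between the two verbal complex-span
WMC indicators (operation span, sentence span — both span tasks with
verbal processing components), giving df 115 and 166. Without these the
plain patterns give 24, 116 and 167.

### Close-fit power

For the RMSEA test of close fit (H0: ε ≤ ε0 vs H1: ε ≥ ε1) the test
statistic is referred to noncentral χ² distributions with noncentrality
`λ = (N−1)·df·ε²`; power is the H1 mass beyond the 1−α quantile of the
H0 distribution, and the minimum sample size for a target power is found
by bisection (power is monotone in N). At ε1 = ε0 the power equals α
exactly. For the df-166 design with ε0 = 0.05, ε1 = 0.08, α = 0.05:
power 0.80 is first reached at N = 95, and N = 148 gives power ≈ 0.966.

## Synthetic battery

The generator emulates a 12-task battery (3 tasks per EF domain plus 3
elementary speed tasks), two conditions per EF task, at the experimental
trial counts of the study design it mirrors (96–192 per condition for EF
tasks; 100–120 for the single-condition speed tasks; 4-alternative
guessing thresholds for the three tasks with four response keys).

Latent structure: speed `s`, WMC and intelligence are standard normal
with correlations 0.46 (speed–WMC), 0.46 (speed–intelligence), 0.76
(WMC–intelligence). The common EF factor is `c = β·s + ζ` (defaults
β = 1, Var ζ = 0: EF coincides with speed — the configuration whose
recovery the end-to-end tests probe); domain factors add optional
domain-specific variance. True drift for person p, task t, condition c
is `μ_tc + λ_t·F_t(p) + e_pt + ε_ptc` with the person-level variance
split 60% general (via the factor), 30% stable task-specific, 10%
condition interaction — a partition chosen once as a realistic
correlated-battery structure. Task drift means and SDs are calibrated to
the battery descriptives the package models (means 1.65–6.25; the
printed SDs are shrunk by the square root of the printed reliability to
yield *true* person SDs, since printed SDs include estimation noise).
Baseline conditions add +1 to the demanding-condition drift. Boundary
separation and non-decision time are log-normal per person around task
means (t0 means chosen so mean RTs land near the corresponding observed
task means); `st0` is uniform on [0.10, 0.20] s. Criterion indicators
load 0.8 on their latent with Gaussian uniqueness, scaled to the
observed indicator means/SDs; five persons lack the binding indicator,
mirroring incomplete criterion data. An optional contamination process
replaces a configured fraction of trials with sub-150-ms uniform guesses
to exercise the preprocessing stage.

What the generator does **not** emulate: stimulus-level congruency
sequences, practice or fatigue effects, session order, RT contaminants
other than fast guesses, and non-Gaussian ability distributions. Passing
recovery tests therefore show the chain is correct and sufficiently
powered under a linear-Gaussian world calibrated to realistic moments —
not that real data meet those assumptions.

## End-to-end variance-decomposition experiment

The pipeline's headline check runs simulate → preprocess → diffusion
fits → scores → speed-regression model at the full battery scale
(148 persons, study trial counts): with β = 1 and zero EF-specific
variance the critical-ratio test on the EF disturbance variance is
non-significant in ≥ 90% of replicates (a type-I-error check, since the
truth is on the boundary); with EF-specific variance at 30% of the
common-EF variance the same test detects it in the majority of
replicates (~85% power in pilots). The second half establishes that the
null result of the first is not an artifact of an insensitive pipeline.
The full scale is retained because detection power collapses at small
samples (near zero at 30 persons) — the sensitivity half of the
demonstration is only meaningful where the design has power.

## Problem sizes used in the test suite

Oracle and recovery tests are sized so that the Monte-Carlo noise of the
oracle sits below the tolerance it checks: 2×10⁵ Euler trials for the
hit-probability and histogram oracles (25-ms bins keep 3σ of bin noise
under the 5%-of-peak band), 10⁵ for the zero-drift mean exit time,
20-point person grids at 192 trials for drift recovery, 200 replicates
at n = 500 for loading recovery and SE coverage, and 10 + 10 replicates
of the full-scale end-to-end experiment.

## Known limitations

* Constant within-trial drift: conflict-task phenomena (fast errors in
  incongruent conditions) are outside the model class by design.
* KS estimation is weakly identified at near-ceiling accuracy; drift
  estimates for such tasks are ordering-stable under the capped
  refinement but their absolute values shrink toward the moment
  estimates.
* The FIML engine covers covariance structures with saturated means —
  no mean-structure hypotheses, ordinal indicators, robust estimators,
  or multi-group models.
* Exact numerical equivalence with any particular legacy estimator
  binary is not claimed; agreement is statistical (same criterion, same
  model, comparable recovery).
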