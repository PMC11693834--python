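# Methods

This note documents the models implemented in `lpexplore`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter for reproducing results.

## Task environment

Each character's hiding location is drawn from a Gaussian
𝒩(μ, σ_n²) truncated to the unit interval by rejection (clipping would put
point masses at the screen edges and bias prediction errors). With per-trial
hazard H the mean μ is re-drawn uniformly on [0.1, 0.9]; the margin keeps the
bulk of the Gaussian on-screen so the realised spread matches the nominal
noise level. Defaults order the three characters as
high-noise/low-volatility (σ_n = 0.12, H = 0.04), low-noise/high-volatility
(σ_n = 0.04, H = 0.25) and intermediate (σ_n = 0.08, H = 0.12), in screen
widths and per-trial probabilities; these keep each pattern learnable within
a ~35-trial session and are fully configurable, as is an explicit
mean-schedule override for hand-crafted hiding patterns. Patterns advance
only on trials in which their character is played.

## Reduced-Bayesian changepoint observer

The observer summarises full run-length inference with one belief B per
character and one relative uncertainty τ = v/(v + σ_n²), where v is the
variance of the belief about the hiding mean. Per trial, with
δ = actual − predicted:

1. predictive SD: σ_pred² = v + σ_n² with v = τ σ_n²/(1 − τ);
2. changepoint probability: Ω = H·U / (H·U + (1 − H)·𝒩(δ; 0, σ_pred²)),
   U = 1/domain width;
3. learning rate α = Ω + (1 − Ω)τ; belief update B′ = B + αδ, projected to
   [0, 1];
4. uncertainty: v′ = Ω·v_reset + (1 − Ω)·τσ_n² + Ω(1 − Ω)·δ²(1 − τ)².
   The middle term is exact conjugate shrinkage (the no-changepoint branch),
   the first the changepoint reset, the last the spread between the two
   branch posterior means. τ_reset = 0.5 corresponds to v_reset = σ_n², the
   uncertainty after one observation of a freshly drawn mean — which is what
   a full run-length filter reports immediately after a detected changepoint.

This is a faithful reconstruction of the reduced-Bayesian observer family
for volatile Gaussian environments, not a bit-level replica of any specific
fitted implementation; every constant (hazard belief H = 0.1, assumed noise
σ_n = 0.08, τ_reset = 0.5, EMA decay λ = 0.5) is surfaced in `LearnerConfig`.
H is a single subjective value for all characters because observers are not
told the true volatility levels; σ_n is fixed rather than estimated online to
keep the filter identifiable on ~35-trial sessions. Against a full Bayesian
run-length filter (implemented independently as a test oracle) the τ
trajectory agrees to a mean absolute difference of ≈ 0.05 on 200-trial
volatile sequences, with the residual disagreement concentrated in the one
to two trials after each changepoint.

**Anchoring.** By default the filter is conditioned on the participant's own
behaviour: the belief carried into each update is the participant's current
prediction, so B′ is the model's forecast of the *next* prediction and all
derived quantities (Ω, α, τ, expectations) are statements about the
participant's learning. In this mode the regression covariate PE =
|actual − predicted| is simultaneously the behavioural and the
model-consistent error. Autonomous agents instead run the filter on their
own persistent belief (`anchor="belief"`).

**Derived covariates.** LP = PE_{t−1} − PE_t within character (undefined on
each character's first trial; state persists across leave/return visits, so
returning to a character does not reset its LP). Expected PE is the mean
absolute deviation of the predictive distribution, √(2/π)·σ_tot with
σ_tot² = v + σ_n². Expected LP is the exponentially smoothed current PE
(λ = 0.5, a two-to-three-trial memory matching the definition of LP as a
two-trial change) minus expected PE: positive when current errors exceed
what the learner should achieve next, zero at convergence. Novelty is
−(number of trials a character has been played), z-scored across the
analysis sample like every other continuous predictor.

## Behavioural coding

A trial is a *leave* iff the next trial uses a different character; the label
sits on the trial preceding the switch so covariates are those available at
the decision point. The final trial is censored, not coerced to stay. Each
leave yields one choice event (chosen vs the unique alternative); events
whose chosen character was never visited, or whose alternative was never
visited, carry no expectations and are excluded from choice modelling.
Inclusion requires ≥ 10 trials with each of the three characters by default
(configurable). The `time` covariate is the session-level trial index.

## Decision models

Performance slopes come from a linear mixed model
PE ~ within-character trial with by-participant random intercepts and slopes
(statsmodels `MixedLM`, REML); a participant's score is the fixed slope plus
their empirical-Bayes deviation, and a singular fit falls back to per-child
least squares. Negative slopes index successful learning.

The leave-stay and choice models are binomial GLMMs with participant random
intercepts, estimated by a Laplace approximation to the marginal likelihood
(the random-effect mode is profiled out per group by Newton iteration; the
outer optimisation is L-BFGS-B over fixed effects and log random-intercept
SD). Fixed-effect covariances are conditional on the estimated variance
parameter, as in lme4; Wald z statistics, 95% CIs and odds ratios follow.
On joint simulated data the fit agrees with lme4's `glmer` (also Laplace) to
~1e-3 in coefficients, variance and log-likelihood. AIC = 2k − 2ℓ and
BIC = k·ln n − 2ℓ with k counting fixed effects plus the random-intercept SD
and n the number of observations. Boundary fits (σ → 0) are valid and reduce
to plain logistic regression; diverging coefficients (|β| > 20) raise a
separation error rather than returning numbers.

The leave-stay model includes the main effect of performance alongside its
interactions (the interaction-only variant is a constructor flag); rows with
undefined LP are dropped listwise and counted. Marginal effects of novelty
and LP at performance = ±1 SD are linear combinations β + level·γ with exact
(delta-method) standard errors from the fixed-effect covariance.
Multicollinearity is checked by VIF_j = 1/(1 − R²_j); a rank-deficient
design is an error naming the collinear columns.

The choice model is fitted on differential predictors. Because no canonical
response coding exists for "which of two options", the two options of each
event are put in a seeded random order, the response is "chose option 1",
and each predictor is value(option 1) − value(option 2); the fit is
invariant (up to intercept sign) to relabelling, which the test suite
verifies. The expectation-based predictor set (Δnovelty, Δexpected LP,
Δexpected PE) and the history-based set (Δnovelty, ΔLP, ΔPE) are compared by
AIC/BIC on the identical response vector, with events lacking either set's
values removed before both fits.

## Synthetic cohorts

Simulated children run the observer in autonomous mode, predict belief plus
truncated-Gaussian motor noise (SD 0.06), and decide through the same
covariate definitions the analysis computes: leave probability is a logistic
function of (standardised) PE, LP, novelty, time, plus performance
interactions and a per-child baseline (SD 0.5 on the logit scale, which the
fitted random intercept absorbs); after a leave, the choice between the two
alternatives is a softmax on differential novelty, expected LP and expected
PE. Default decision coefficients are the study conditions: leave
coefficients (per SD) PE −0.01, LP 0.0, novelty 0.25, time −0.12,
performance×LP 0.49, performance×novelty 0.73 (the main effects of novelty
and LP are back-derived from the marginal-effect pattern those interactions
imply at ±1 SD of performance), and choice coefficients novelty 0.30,
expected LP 0.35, expected PE −0.21.

Because agents cannot z-score covariates online, their policies standardise
by fixed reference scales — constants calibrated once on a 400-agent pilot
under the default policy with fixed 40-trial sessions and iterated once to
self-consistency (frozen in `cohort.REFERENCE_SCALES`; e.g. SD 0.127 for PE,
6.47 for pick counts, 0.111 for Δexpected LP). The analysis z-scores
empirically, so generating coefficients live on the fitted per-SD scale up
to small endogenous shifts in covariate spread.

Individual differences follow a log-normal impairment multiplier m
(SD of log m = 0.5) scaling motor noise and, when `impair_learner` is on
(the default for realism), the agent's subjective hazard — producing the
graded continuum of PE slopes the performance model estimates. With
`impair_learner` off the generator is exactly correctly specified: agents'
decision covariates equal the analysis's refit values. The calibration and
recovery experiments that need a known best case use that switch; the
session-length and realism checks use the harder default.

Session termination follows the study rules: a per-trial quit probability of
0.056 after 10 trials of engagement plus a hard stop once any character has
been played 35 times, yielding ≈ 26 trials per session on average (SD ≈ 15),
matching the reported session statistics within 10%; fixed-length sessions
are available for controlled experiments.

**What the generator does not emulate:** attention and fatigue dynamics,
experimenter prompts, elapsed wall-clock time, 2-D screen geometry, and any
dependence of motor noise on target position. Passing calibration and
recovery on these cohorts shows the pipeline is consistent and well
calibrated when its assumptions hold — it does not by itself establish that
children's data satisfy those assumptions.

## Experiment design choices

- Type-I calibration uses 500 replicates of 20 children × 30 fixed trials
  under a null policy (all decision coefficients zero except intercepts);
  rejection is a Wald p < .05 on any non-intercept fixed effect. Observed
  rates are ≈ 0.05 for both models.
- Choice-coefficient recovery uses 100 replicates of 100 children × 40 fixed
  trials with the study-condition coefficients; the generating values are
  recovered within 2 SEs in well over 90% of replicates. These experiments
  pass the ground-truth latent performance to the fits, isolating decision-
  model recovery from performance-estimation noise; pipelines on real data
  use estimated slopes, which attenuates interaction estimates (visible in
  the README example).
- Model selection uses 100 cohorts of 87 children (the study's analysed
  sample size) × 40 fixed trials under the correctly-specified
  expectation-driven generator; the expectation-based model wins on AIC in
  ≈ 80% of cohorts. This rate sits near the decision boundary and varies by
  several points across seeds at this cohort count.
- Recovery and calibration experiments disable the inclusion filter (the
  ground truth is known and sessions are fixed-length); the study-emulating
  pipeline applies it with the configurable ≥ 10-trials-per-character rule.

## Numerical details and degenerate inputs

τ is capped at 0.975 so the implied belief variance stays finite; the
conjugate-shrinkage recursion gives the exact harmonic decay
τ_{n+1} = τ_n/(1 + τ_n) on stable stretches. Truncated draws use rejection
sampling throughout. z-scoring uses the population SD and maps constant
input to zeros. Empty sessions, unsorted or duplicated trial indices,
out-of-range locations, unknown characters, non-binary responses,
rank-deficient designs and under-sized choice-event tables all raise typed
errors with the offending column or participant named. All stochastic code
paths take an explicit seed or Generator; cohort simulation spawns
per-child seeds from one `SeedSequence`, so datasets are byte-identical
across runs of the same seed.

## Known limitations

- The observer fixes its noise belief; online noise estimation (and
  per-child maximum-likelihood fitting of learner hyperparameters) is out of
  scope.
- The GLMM supports a single scalar random intercept per group — the
  structure the analyses specify — not random slopes or crossed effects.
- Wald inference is asymptotic; with very few events per parameter the
  choice-model calibration will degrade before the leave-stay model's.
- Generating coefficients and fitted coefficients share a per-SD scale only
  as well as the frozen reference scales match the realised covariate
  spread, which shifts slightly whenever policy coefficients move the
  behaviour away from the calibration conditions.
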