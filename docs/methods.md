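# Methods

## The criterion and its false-positive rate

A subject reaches criterion at the first trial *t* with at least *k*
correct choices among the last min(*t*, *w*) trials (defaults *k* = 10,
*w* = 12).  Short windows count by default (`allow_short_windows=True`):
a perfect opening run of 10 meets the rule at trial 10.  The convention is
exposed as a switch because published criteria rarely state it; with it
off, attainment is only possible from trial *w* onward.

Two routes give the probability that a Bernoulli(*p*) agent meets the
criterion by horizon *t*:

- **Exact**: a dynamic programme whose state is the last *w* − 1 outcomes
  encoded as an integer (2^(w−1) = 2048 states at *w* = 12) plus an
  absorbing "met" state.  Early trials need no special casing: unobserved
  leading positions hold zeros and the window is then the whole prefix,
  so the trailing-window count is always popcount(state) + next outcome.
  The DP is guarded at *w* ≤ 20 and is tested for exact agreement with
  brute-force enumeration of all 2^t sequences at *t* ≤ 15.
- **Monte Carlo**: one cohort of simulated agents evaluated cumulatively
  at every horizon.  Reusing a single cohort matches how attainment
  accrues in a real study and makes the curve nondecreasing by
  construction; per-horizon independent simulation was rejected for that
  reason.

A single criterion definition (`ttc`, vectorized as `ttc_batch`) backs the
data path, the simulation path and the DP cross-checks, so the three can
never drift apart.

## Individual learning curves

Each subject × task sequence is fitted with maximum-likelihood logistic
regression of outcome on the 1-based trial index (Newton's method on a
centred covariate; estimates match `statsmodels` GLM to ~1e-8).  The raw
per-trial index is used rather than a z-scored one: the slope's sign and
its empirical p are invariant to affine covariate changes, and
log-odds-per-trial is the interpretable unit.

With a strictly increasing scalar covariate the MLE is finite if and only
if correct and incorrect trials interleave; all-correct, all-incorrect and
clean block patterns (0…01…1) are detected *a priori* and flagged as
separated with a signed-infinity slope marker instead of returning a
pseudo-converged huge coefficient.  Fits on fewer than 10 trials warn;
fewer than 2 is an error.

**Null distributions.**  Each observed slope is compared against 1000
simulated chance agents (p = 0.5) with the same trial count, fitted by a
vectorized batch Newton solver (all agents share one design matrix, so a
thousand fits cost milliseconds).  The empirical p is the plain proportion
of null slopes ≥ the observed slope; it may be exactly 0, matching the
proportion definition, with a conservative (r+1)/(n+1) variant behind a
flag.  Separated null agents keep their signed-infinity markers so the
≥ ordering stays well defined — dropping them would shrink the null's
upper tail and make the test anti-conservative.  An observed +∞ slope is
compared against the null's +∞ markers only (flagged with a warning);
for short perfect runs this still yields a small p, which is why a
12-trial all-correct subject classifies as a slope learner.

**Accuracy assessments.**  Initial accuracy is the proportion correct in
the first min(n, 12) trials, classified against the empirical 5th/95th
percentiles (smallest value with ECDF ≥ q) of 10,000 simulated chance
agents of the same length; classification is strict (> upper, < lower).
The length-matched null is the natural convention for subjects with fewer
than 12 trials.  Overall and post-criterion accuracy use the exact
two-sided binomial test with the doubled-smaller-tail convention, capped
at 1 (stated explicitly because two-sided exact conventions differ; at
p = 0.5 it coincides with the minimum-likelihood convention).
Post-criterion accuracy covers trials strictly after the TTC trial and is
absent when the criterion was unmet or met on the final trial.

**Estimator bias.**  The ML logistic slope carries a positive O(1/n)
finite-sample bias (first-order Cox–Snell term; ≈ +0.010 at a true slope
of 0.1 over 60 trials).  `ml_slope_bias` computes this closed form, and
recovery tests compare mean estimates against truth *plus* this term.
The empirical-p test is unaffected: observed and null slopes share the
bias.

## Population model

The trial-level mixed model is binomial with a logit link:
success ~ trial_z + task_c + colour_c (+ trial_z × task_c), random
intercepts per subject and, by default, random slopes for the
trial × task interaction and colour (the maximal structure; whether
lower-order trial and task slopes belong in it is left to the
`RandomStructure` descriptor, since both readings are defensible).
Age and sex are deliberately not predictors.  Continuous trial number is
z-scored with the n−1 sample SD over included rows; binary codes are
centred on observed means (−0.5/+0.5 under balance); the coding map is
stored on the design so fits are reproducible.

Estimation maximizes the Laplace-approximated marginal likelihood, written
in-package: random effects are parametrized b_i = L·u_i with u_i ~ N(0, I)
and L the covariance Cholesky factor, so the per-subject inner problem
(penalized logistic mode finding, Newton with step halving) is strictly
concave and the objective is defined at singular covariances.  The outer
optimization is BFGS with finite-difference gradients (step 1e-6; the
inner solves are converged to 1e-11 so differencing noise is negligible);
standard errors come from the finite-difference observed information over
all parameters (falling back to the fixed-effect block when a variance
sits on the boundary).  On a shared cohort the fit agrees with
lme4::glmer (also a Laplace method) to ~1e-3 in coefficients, SEs and
log-likelihood; that agreement is enforced in the test suite with
`Rscript` as an independent oracle.

Convergence failure triggers a fixed simplification ladder — drop slope
correlations, drop the colour slope, drop the interaction slope,
intercepts only — and the rung used is recorded on the fit and warned
about.  Inference is by likelihood-ratio tests: the full model against a
null without trial and task terms, then drop-one tests starting with the
interaction; main effects are tested only if the interaction is
non-significant, in a reduced model without it, with the random structure
held fixed across each comparison for nestedness.  The trimmed refit
truncates every sequence to its first 40 trials per task and is compared
qualitatively (signs, overlapping 95% Wald intervals).

## Synthetic cohorts

Generators are marginal-probability models: a per-trial success
probability plus independent Bernoulli draws.  Phenotypes: chance agents
(p = 0.5), constant-bias agents (immediate colour preference), gradual
learners (logistic in trial), step learners, and perseverative reversers
— a monotone logistic ramp from below chance (initially choosing the
formerly rewarded stimulus) toward a learned asymptote, the simplest
process matching the reversal phenotype.  Win-stay/lose-shift and other
strategy dynamics are out of scope, so trial-to-trial autocorrelation
beyond the mean function is absent; passing tests demonstrate calibration
and recovery under independence, not robustness to strategic choice
sequences.

Default cohorts have 32 initial-task subjects, each advancing to the
reversal with probability 18/32; initial-task trial counts are
right-skewed (log-normal, mean ≈ 36, clipped to 4–136) and reversal
sequences longer (normal, mean ≈ 68, same clipping), giving cohorts of
roughly 2000–2500 trials with the heterogeneity and dropout a field study
produces.  Sessions are capped at 50 trials/day; the reversal swaps the
rewarded colour; session dates let inter-task intervals (1–11 days) be
computed from the data.  One master seed spawns per-subject substreams,
so cohorts are reproducible while subjects stay independent.
`generate_glmm_cohort` instead embeds exact known fixed and random
effects on the model's own standardized scale, for parameter-recovery
checks.

## Problem sizes and numerical choices

Simulation scales mirror the analysis defaults: 10,000 agents for the
false-positive curve and initial-accuracy percentiles, 1000-agent
individual nulls, 32-subject cohorts.  Calibration checks use 500 chance
subjects; mixed-model coverage uses 40 replicate cohorts (Monte-Carlo SE
of the coverage estimate ≈ 2 points).  Wald 2-SE coverage of the Laplace
fit at 32 subjects runs near 92% — slightly under nominal, the familiar
cost of plugging in variance components — which the ≥90% recovery check
reflects.

Ties in the empirical p count in favour of the null (≥).  LR statistics
are clipped at zero within optimizer tolerance; a comparison of a model
with itself returns df = 0, p = 1.  Dates parse as mm/dd/Y (with m/d/yy
and ISO fallbacks) and degrade to opaque strings with a warning, since
they only matter for inter-task intervals.  Session-cap violations warn
rather than fail: the 50-trial cap is a protocol rule a user's data may
legitimately break.

## Known limitations

- The Laplace approximation can bias variance components at small cluster
  counts; adaptive quadrature is not implemented.
- Separated slope fits have no finite magnitude; cross-task slope
  correlations exclude them (with a count), and their classification
  rests on the null's separation rate.
- The criterion's literal wording in some protocols ("runs of ≥10
  correct") is stricter than the count-within-window rule implemented
  here; the count rule is the operative definition throughout.
- Real choice sequences may be autocorrelated (momentum, side bias);
  every null here assumes exchangeable Bernoulli trials.
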