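# revlearn

Trial-level analysis of learning in binary two-choice tasks — for
researchers in animal cognition and behavioural ecology who score
discrimination and reversal experiments as sequences of correct/incorrect
choices and need to decide, per individual, whether learning actually
happened.

## The problem

The conventional "learned" threshold in such tasks is **trials-to-criterion
(TTC)**: the first trial at which an individual has made at least *k*
correct choices within the last *w* trials (typically 10 of 12).  The rule
is justified by a single-block binomial argument — at chance,
P(≥10 of 12 correct) = 79/4096 ≈ 0.019 — but the criterion is applied with
a *sliding* window, so every additional trial is a fresh opportunity to
pass.  The false-positive probability therefore grows with participation:
for a chance-level (p = 0.5) agent it is ≈9% by trial 25 and >32% by trial
75.  In field settings, where trial counts vary enormously across
individuals, this makes TTC alone uninterpretable as evidence of learning.

## What the package computes

- **Criterion audit** (`revlearn.criterion`): TTC under a configurable
  x-of-y rule; the exact attainment probability
  P(TTC ≤ t | p) by dynamic programming over the 2^(w−1) recent-outcome
  states; a Monte-Carlo false-positive curve over simulated chance agents.
- **Individual learning curves** (`revlearn.learning_curves`): per-subject
  logistic regression logit P(correct at trial t) = α + β·t; the slope β
  (log-odds/trial) is tested one-sidedly against an empirical null of 1000
  simulated chance agents with the same trial count
  (p = #{β_null ≥ β_obs}/1000).  Perfectly or quasi-separated sequences are
  flagged and carried as signed-infinity markers.  Initial accuracy (first
  12 trials) is classified against simulated 5th/95th chance percentiles;
  overall and post-criterion accuracy use exact two-sided binomial tests.
- **Population model** (`revlearn.population_model`): binomial GLMM
  logit P(y_ij = 1) = β₀ + β₁·trial_z + β₂·task_c + β₃·colour_c
  (+ β₄·trial_z·task_c) + b_i'z_ij with per-subject random intercepts and
  slopes, fitted by maximizing the Laplace-approximated marginal
  likelihood (validated against lme4::glmer), with likelihood-ratio
  full–null and drop-one tests and a trimmed (first-40-trials) robustness
  refit.
- **Classification report** (`revlearn.classify_report`): a
  participant-summary table combining all metrics, plus cross-task Pearson
  slope correlation and the Spearman correlation of inter-task interval
  with reversal accuracy.
- **Synthetic cohorts** (`revlearn.synthetic_data`): seeded generators for
  chance agents, constant-bias birds, gradual (logistic) learners, step
  learners and perseverative reversers, assembled into two-task cohorts
  with realistic trial-count heterogeneity, dropout and 50-trial daily
  session caps.

## Worked example

The numbered scripts under `analysis/` run the full workflow on a
simulated cohort (32 subjects, 14 of which advance to the reversal under
this seed; 1949 trials total):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_false_positive_audit.py
python analysis/03_individual_learning.py
python analysis/04_population_model.py
python analysis/05_cross_task_consistency.py
```

`02_false_positive_audit.py` prints the core inflation result — simulated
and exact attainment proportions for chance agents:

```
criterion met by trial  12:   1.9% simulated |   1.9% exact
criterion met by trial  25:   9.3% simulated |   9.2% exact
criterion met by trial  50:  21.8% simulated |  21.6% exact
criterion met by trial  75:  32.1% simulated |  32.2% exact
```

At 12 trials the sliding criterion matches the single-block logic (0.019);
by 75 trials nearly a third of chance agents have "reached criterion".

`03_individual_learning.py` classifies every subject both ways:

```
AL: 32 subjects
  criterion (TTC) calls 16 learners; slope test calls 10
  TTC-only 7 | slope-only 1 | both 9
```

The criterion over-calls learning relative to the slope test (seven
chance-streak false positives) and misses one gradual improver — the
disagreement pattern the slope-based analysis is designed to expose.

`04_population_model.py` recovers the cohort-level trends with the mixed
model (the generating cohort improves across trials; reversal is harder):

```
full-null comparison: chi2(3) = 21.09, p = 0.0001
trial x task interaction: chi2(1) = 0.07, p = 0.791
  trial_z: beta = +0.538 (se 0.125), chi2(1) = 19.11, p = 1.2e-05
```

## Command line

The same stages are available as a console script, e.g.:

```sh
revlearn fp-curve --window 12 --required 10 --horizon 75 --agents 10000 --seed 1
revlearn cohort --subjects 32 --seed 1 --out synth.csv
revlearn classify --input synth.csv --out report.tsv --seed 1
revlearn population --input synth.csv --trim 40 --seed 1
```

## Analysing your own data

`read_trials_csv(path, strict=True)` ingests a long-format CSV with the
columns `date, ID, age, sex, task, colour, session, trial, succ, cumsum,
cumTrial, crit, critTrial` (one row per trial; `succ` ∈ {0,1}; `cumTrial`
pooled across sessions), validates the derived columns, and returns one
trial sequence per subject × task ready for every analysis above.
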