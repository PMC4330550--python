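# Methods

This note documents the models, estimation procedures, synthetic-data design
and numerical conventions implemented in `revlearn`, together with the design
choices that were genuinely open and the limitations a user should know about.

## Task model

The environment is a two-alternative probabilistic reversal-learning task.
One stimulus is designated correct; choosing it is rewarded (+1) with
probability `p_reward_correct` (default 0.8) and punished (−1) otherwise.
Choosing the other stimulus inverts those probabilities. A *block* ends — and
the correct stimulus flips — at the first trial on which both hold:

1. the number of correct choices since the last reversal has reached the
   block's criterion, an integer drawn uniformly from {6, …, 10} per block, and
2. the current streak of consecutive correct choices is at least 3.

The reversal takes effect from the next trial. "Correct choice" means a
choice of the currently correct stimulus, regardless of the sampled outcome:
with probabilistic feedback, outcome-based counting would make the criterion
ambiguous.

One edge case is worth noting: condition 2 can hold a block open past the
nominal maximum of 10 correct choices if the chooser never strings 3 correct
choices together after reaching the criterion. For any learner that does
reach criterion the count at reversal lies in [6, 10]; for a pathological
alternating chooser the count is unbounded. Tests assert the implied
guarantees (count ≥ criterion and streak ≥ 3 at every reversal; count exactly
in [min, max] for a perfect chooser).

Sessions are `n_runs × trials_per_run` trials (default 2 × 60) with task
state persisting across runs. Missed trials (injected with
`miss_probability`, default 0) carry no choice and no outcome, and do not
advance the reversal counters. Outcomes are coded on a unit scale (±1); the
monetary magnitudes of the original task are configuration metadata only —
this keeps values, prediction errors and the softmax temperature on a common,
interpretable scale.

## Learning models

All three models share `RPE_t = R_t − V_t^chosen` and a logistic softmax on
the value difference, `p(A) = 1/(1 + exp(−(V_A − V_B)/τ))`, τ > 0.

* **Rescorla–Wagner** (2 free parameters): `V_chosen += α·RPE`; the unchosen
  value is untouched.
* **Risk-sensitive** (3): separate learning rates for positive and negative
  prediction errors on the chosen option, `V_chosen += α^{±}·RPE`. The
  asymmetry lets the model express optimistic/pessimistic (risk-sensitive)
  valuation.
* **RSAV** (5): additionally pushes the unchosen value in the opposite
  direction, `V_unchosen −= α_u^{±}·RPE`, with the sign branch taken on the
  *chosen* option's prediction error exactly as the update is written. In a
  two-option reversal task, feedback about the chosen option is evidence
  about the other one.

Conventions (configurable where noted):

* initial values `V₀ = (0, 0)` — a symmetric prior consistent with early
  prediction errors of magnitude ≈ 1 (configurable);
* values persist across the runs of a session (`reset_between_runs=False` by
  default; when enabled, the likelihood also restarts at run boundaries);
* an exactly zero prediction error takes the positive-rate branch — a
  measure-zero event under continuous values, fixed for bit-reproducibility.

The chosen-option update is a convex combination, so RW and risk-sensitive
values stay in [−1, 1]. The RSAV unchosen update is **not** contractive: the
unchosen value is unbounded, and on adversarial choice/outcome sequences the
two values can grow multiplicatively (growth is capped by 3^n over n trials,
so any session-length replay is finite, but float64 can overflow on random
sequences tens of thousands of trials long). This is a property of the model
as written, with consequences discussed under *Limitations*.

## Likelihood and fitting

The objective is the mean per-trial log probability the model assigns to the
observed stay-or-switch behavior. For every trial with a defined predecessor
(the previous non-missed trial), the softmax — evaluated on values updated
through that predecessor — gives the probability of repeating versus changing
the previous choice; with two options this equals the probability of the
observed choice. The first valid trial contributes no term; missed trials
contribute neither a term nor a value update, so inserting misses leaves the
likelihood unchanged.

The *mean* (rather than summed) log-likelihood is used so that fit quality is
comparable across subjects with different numbers of valid trials, and AIC is
kept on the same per-trial scale: `AIC = −2·logL + 2M/N`, with `M` free
parameters and `N` the number of non-missed trials. A likelihood written with
switch/stay counts as exponents inside the log cannot be normalized to this
scale self-consistently, so the per-trial mean is the convention implemented
throughout; only model *ranking* matters for the selection stage, and ranking
is invariant to the choice.

Estimation is a seeded global-then-local search: `restarts` independent runs
of differential evolution over box bounds (rates in [0, 1], τ in
[0.01, 10]), each refined with bounded L-BFGS-B. Likelihood ties are broken
by the smaller temperature, then lexicographically smaller rates, making fits
deterministic given the seed. A grid-search oracle test guarantees the
optimizer dominates an exhaustive 0.01-step grid on the 2-parameter model.
The *canonical* fit maximizes the unweighted mean of per-subject mean
log-likelihoods over one shared parameter vector — the parameter set used to
build common RPE regressors for all subjects.

## Model selection

Per-subject log model evidence is approximated from AIC on the total-data
scale, `log evidence ≈ −0.5 · N · AIC = logL_total − M`. Random-effects
selection treats the model identity as a random effect: population model
frequencies follow a Dirichlet (uniform prior, α₀ = 1 per model) whose
posterior is found by the standard variational iteration — subject-wise
posterior assignments `u_nk ∝ exp(evidence_nk + ψ(α_k) − ψ(Σα))`, Dirichlet
counts updated from the assignments — until `max |Δα| < 10⁻⁶`. Exceedance
probabilities `P(r_k > r_j ∀ j≠k)` are estimated by seeded Monte-Carlo
sampling from the posterior (10⁶ samples by default; closed-form Beta checks
cover the 2-model case).

## Synthetic cohorts

The generator reproduces the study design it emulates: two groups of RSAV
agents — 19 "adolescents" and 17 "adults" — each playing 2 × 60 trials.
Per-subject parameters are drawn independently per parameter from truncated
normals (rates on [0, 1], τ on (0.01, 10]) centered on the published
group-mean estimates for this design:

| group | α_c⁺ | α_c⁻ | α_u⁺ | α_u⁻ | τ |
|---|---|---|---|---|---|
| adolescent (n = 19) | .62 ± .07 | .69 ± .05 | .78 ± .07 | .63 ± .04 | 1.9 ± .2 |
| adult (n = 17) | .45 ± .10 | .49 ± .05 | .72 ± .08 | .58 ± .06 | 2.4 ± .2 |

The printed dispersions are standard errors of the mean (the reported group
t-statistics are consistent with that reading), so the subject-level SD is
recovered as `SEM·√n`. Truncation to [0, 1] is asymmetric around means like
0.69, so the realized population mean sits slightly below the nominal one
(≈ 0.03 for the adolescent α_c⁻); tests compare sample means against the
analytic truncated-normal mean. Generating agents never miss by default;
miss injection is available for robustness checks. Every record regenerates
bit-identically from (spec, master seed), and ground-truth parameters are
retained for recovery scoring.

What the generator does *not* emulate: reaction times, null trials (they
matter only for event timing in neuroimaging, and regressor onsets here are
synthetic), age as a continuous covariate, and — importantly — human-level
task performance (see *Limitations*).

## Group analysis and regressor export

Behavioral summaries per record: percent of non-missed trials choosing the
currently correct stimulus; number of switches (choice differs from the
previous non-missed choice); and the mean, over switch events, of the run
length of consecutive punished trials immediately preceding the switch.

Group comparison of fitted parameters mirrors the classical analysis: a
mixed-design ANOVA (between-subject factor group, within-subject factor
parameter; split-plot sums of squares via `pingouin.mixed_anova`, no
sphericity correction) followed by per-parameter two-sample t-tests with
Bonferroni correction over the 5-parameter family. Degenerate (zero-variance)
inputs are flagged rather than fatal. A summary-statistics t-test
(`ttest_from_summary`) reconstructs group tests from printed means and SEMs.

For regressor export, each subject's trial-wise RPEs are split into three
equally sized bins (negative / neutral / positive) by sorting (stable, so
ties break by trial order; remainders go to the earlier bins); the reported
boundaries are the largest RPE of the negative and neutral bins. The events
table holds one cue row (chosen value) and one feedback row (RPE, bin label)
per trial, onsets in seconds, durations 0 (impulse regressors), continuous
modulators mean-centered. Pipeline onsets are synthetic (9 s per trial, the
task's average trial duration).

## Pipeline

`run_pipeline` chains the stages — simulate cohort, fit all three models per
subject, model-comparison table with group BMS (per group and overall),
canonical RSAV fit, parameter group tests, RPE traces/bins/regressor export —
and writes per-stage JSON/TSV artifacts plus a versioned, schema-validated
`results.json` and a human-readable report. All randomness derives from the
single config seed; per-subject fits use per-subject derived seeds, so
results are independent of execution order. Presets: `paper` (full 36-subject
design) and `tiny` (4 subjects, 2 × 15 trials; the smoke-test scale used in
CI-style runs).

## Problem sizes used in checks

Contingency rates use 10⁵ simulated trials (binomial 3σ bands). Model
identification uses one 36-subject cohort fitted with all three models.
Parameter recovery uses 10 replications of cohorts simulated at the exact
group-mean vectors. Nesting equivalences replay 10⁴ random sequences;
finiteness checks cover ~10⁶ updates as 8,400 session-length sequences.

## Limitations

* **Generative pathology of the fitted RSAV model.** Simulated RSAV agents at
  the group-mean parameters are strongly perseverative: the unbounded
  anticorrelated update lets the unchosen value drift far negative, a single
  lucky outcome then produces an outsized prediction error, and the adaptive
  reversal rule — which flips contingencies exactly when the agent performs
  well — strands perseverative agents on the wrong stimulus. Their accuracy
  is consequently *below* chance (the README example's 27.5% is typical),
  unlike the ≈ 74% reported for human subjects in this design. Fitting a
  model to behavior and generating behavior from the fitted model are
  different uses, and this model family is only validated for the former.
* **Weak identifiability at the study scale.** In the perseverative regime
  the switch/stay likelihood has a ridge (value scale trades off against
  temperature), and maximum-likelihood estimates of the negative-RPE learning
  rates are noisy and biased low — demonstrably not consistent even at 10×
  the session length. The recovery quantities computed by
  `scripts/acceptance.py` make this visible: cohort-mean recovered α_c⁻ falls
  short of the generating value by roughly 0.15–0.30 depending on the group.
  The group *direction* (adolescent α_c⁻ > adult α_c⁻) is preserved in
  simulated cohorts, but with far less power than the original human
  contrast; users should not expect significance at n = 36 from synthetic
  cohorts.
* The AIC-based evidence proxy ignores parameter-volume effects beyond the
  count penalty; protected exceedance probabilities and hierarchical
  (empirical-Bayes) fits are out of scope.
* The mixed ANOVA applies no sphericity correction, matching the classical
  reporting convention for this analysis.
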