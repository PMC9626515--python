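# Methods

## The task

The probabilistic reversal learning (PRL) task implemented here is a
two-choice serial discrimination.  On every trial the subject picks one of
two abstract stimuli; one stimulus is designated correct and yields positive
feedback (+1), the other negative feedback (-1).  Two complications make the
task diagnostic of flexible learning:

* **Probabilistic errors.**  Each discrimination stage plants a small number
  of positions (0-4, cycled through a shuffled balanced sequence per block)
  at which a *correct* choice is misleadingly punished.  Positions are drawn
  uniformly without replacement from the stage's criterion range, so a
  planted error may fall on the very first correct response of a stage.
* **Reversals.**  Once the subject has accumulated a criterion number of
  correct-stimulus choices (drawn uniformly from 10-15, counting
  misleadingly punished ones), the contingency silently flips.  A block has
  11 stages, hence 10 reversals; a session has 3 blocks.

Design choices where the task description leaves room: stimulus identity
(0/1) is the unit of choice — screen position is randomized in the real task
and carries no information, so it is not simulated; incorrect choices always
receive negative feedback (misleading *positive* feedback for errors is not
part of the task); simulated runs carry a per-block safety cap
(`max_trials_per_block`, default 400) because an unlucky or poorly
parameterized agent may never reach criterion, which human subjects did.
Response times are neither simulated nor analyzed.

## The models

Both models score the two stimuli with values/attractions q and choose via
a softmax, `P(choice = 1) = 1 / (1 + exp(-beta (q1 - q0)))`, with inverse
temperature `beta in [0, beta_max]` (`beta_max = 10`).  Values reset to 0 at
block boundaries (new stimuli).  Outcomes are coded +1/-1.

**Reward-punishment (RP).**  A Rescorla-Wagner learner with separate
learning rates for rewarded and punished trials.  The outcome's sign selects
the rate for the whole trial — `a_rew` after a win, `a_pun` after a loss —
and, in the default *mirrored* variant, the unchosen stimulus is updated
toward the sign-flipped outcome at the same rate:

    q[c]  += a * (o - q[c])          a = a_rew if o > 0 else a_pun
    q[1-c] += a * (-o - q[1-c])      (mirrored variant, default on)

The mirrored update is the standard choice for a two-option task whose
contingencies are perfectly anticorrelated; a `mirrored=False` flag gives
chosen-only updating.  With outcomes in {-1, +1} and zero initialization all
values remain in [-1, 1].

**Experience-weighted attraction (EWA).**  Each stimulus carries an
experience weight `n` decayed at rate `rho` and an attraction updated as

    n'   = rho * n + 1
    q[c] = (q[c] * (1 - a) * rho * n + o) / n'

so `rho = 0` collapses to memoryless tracking of the last payoff and
`rho -> 1` freezes learning as experience accumulates (a candidate
mechanism for perseveration).  The old attraction is weighted by the
*decayed* experience `rho * n`; attractions are passed to the softmax
unnormalized.  Since no update equations are printed for either model in
the task literature this package follows, both recursions follow the
conventions of the hierarchical-Bayesian modeling family commonly used for
this task, and the likelihood code is checked against hand-traced oracles.

## Hierarchical inference

Per group (groups are always fitted separately), subject-level parameters
live on an unconstrained scale: `theta_raw[i,k] ~ Normal(mu[k], sigma[k])`
with priors `mu ~ Normal(0, 1)` and `sigma ~ half-Cauchy(0, 5)`.
Constrained parameters are the inverse-probit transform `Phi(theta_raw)`
for rates/decays and `Phi(theta_raw) * beta_max` for the inverse
temperature.

Sampling uses a No-U-Turn sampler written for this package: slice-variable
tree doubling with the no-U-turn criterion, dual averaging of the step size
to a 0.8 target acceptance statistic, and a diagonal metric adapted over
expanding warmup windows.  The posterior is parameterized non-centered
(`theta_raw = mu + sigma * z`), which removes the funnel geometry small
groups otherwise produce.  Gradients of the trial-level likelihoods are
analytic — forward accumulation of dq/dparam through the value recursion —
and compiled with numba; the rate-selection branch is treated as locally
constant, exact almost everywhere.  Gradient code is verified against
finite differences and a pure-numpy reference in the test suite.

Chains (default 4) draw independent seeds from a master seed and run
sequentially, so results are bit-reproducible for a given configuration.
`n_samples` counts total draws per chain including `n_warmup` burned draws
(defaults 20,000 / 2,000, matching a publication-scale analysis; tests and
the acceptance run use scaled-down configurations stated below).
Convergence is summarized by split-chain Gelman-Rubin R-hat for every
sampled and constrained parameter (computed in-package, cross-checked
against arviz); any R-hat above 1.1 flags the fit with a warning rather
than raising.  Model comparison uses subject-level PSIS-LOO via arviz
(LOOIC = -2 elpd_loo; the pointwise unit is the subject — a subject's
summed trial log-likelihood per draw), validated in tests against exact
leave-one-out on a conjugate normal toy model.

## Behavioral statistics

* **Correct responses** count contingency-correct choices — a misleadingly
  punished correct choice still counts.
* **Perseveration.**  After each reversal, the *reversal error* is the first
  punished choice of the previously correct stimulus; the perseverative
  errors are the consecutive further choices of that stimulus immediately
  following it (the run is feedback-independent: a misleading win on the old
  stimulus does not end it, only choosing the other stimulus does).  A
  reversal enters the rate denominator only when at least one perseverative
  error occurred; the rate is errors per qualifying sequence.  Later,
  non-consecutive returns to the old stimulus are not counted.
* **Stay/switch.**  A stay repeats the previous trial's choice; pairs are
  defined from the second trial of each block and never span blocks.
  Reversals do not interrupt pairs (subjects cannot observe them).
* **Cumulative negative feedback** is coded 0-3: 0 after a win; 1 after a
  single loss; 2 after two consecutive losses with a stay between them;
  3 after three consecutive losses with two consecutive stays.  Longer
  loss/stay runs are capped at 3.
* **Regressions.**  Stay/switch is regressed on the previous outcome
  (reward +0.5 / loss -0.5) or the cumulative code (numeric 0-3), group
  (HC +0.5 / AUDP -0.5), and the interaction, with a per-subject random
  intercept.  The random-intercept logistic model is fitted by maximum
  likelihood with adaptive Gauss-Hermite quadrature (15 nodes, centred and
  scaled at each subject's posterior mode; one node recovers the Laplace
  approximation), implemented in-package and validated against R's lme4 on
  identical data (agreement to ~1e-3).  Post-hoc pairwise contrasts (the
  four outcome-by-group cells, or the group contrast at each code level)
  use a single-step max-|z| adjustment under the joint normal law of the
  contrast estimates — a Tukey-type correction — evaluated by fixed-seed
  Monte Carlo (200,000 draws, error < 1e-3 on the p scale).

## Group comparison, PPC, and recovery

Groups are fitted independently, so no joint posterior over the group
difference exists.  Difference draws pair randomly permuted draws of the two
posteriors; each fit's permutation derives from the pairing seed plus the
fit's identity (data hash, model, group), making the difference exactly
antisymmetric in its arguments.  The 95% highest-density interval is the
shortest contiguous interval over sorted draws covering ceil(0.95 n) points;
a parameter differs credibly when the interval excludes zero.

Posterior predictive choices come in two modes.  The default re-simulates
the *full task* per subject for a thinned set of posterior draws (default
500) — simulated choices feed back into the value recursion — and records
per-trial simulated-choice frequencies aligned to the empirical (subject,
block, trial) grid; simulated runs that finish a block early simply stop
contributing to later trials.  The one-step-ahead mode instead computes
each trial's predictive choice probability conditional on the subject's
observed history, averaged over draws.  The modal choice is the most
frequent (or most probable) simulated choice, ties toward stimulus 0.

Parameter recovery uses the one-step-ahead modal choices: full
re-simulations decohere from the empirical trial grid after the first
reversal (their per-trial marginals blur toward 1/2), so their modal
sequence is not a coherent behavior and carries almost no recoverable
parameters — an instructive failure mode we document rather than use.  The
refit dataset pairs the modal choices with the observed outcome sequence
(outcomes are conditioning variables in these likelihoods, not modeled) and
recomputes contingency-correct flags; the model is then refitted with the
same hierarchical configuration and subject-level posterior means are
correlated; when synthetic ground truth exists, correlations against it are
reported alongside.  Even so, modal choices discard the subject's response
stochasticity, which attenuates recovery of the inverse temperature in
particular — recovered subject effects shrink strongly toward the group
mean (the refit's group-level beta sd is roughly a third of the original's),
an intrinsic property of modal-choice recovery worth keeping in mind when
reading recovery correlations.  PPC-based behavioral statistics support a modal mode
(modal choices through the standard statistics) and a weighted mode
(probability-weighted win-stay/lose-shift, where the stay probability of a
pair is p p' + (1-p)(1-p')); the perseveration run statistic has no
per-trial expectation form, so weighted mode reports it from the modal
choices.  When the predictive probabilities are exactly the empirical 0/1
choices both modes reduce to the raw statistics.

## Synthetic cohorts

Because no empirical dataset ships with the package, a generator produces
two-group study datasets with the structure the analysis assumes: 28
AUDP-like and 27 HC-like subjects, 3 blocks each, subject parameters drawn
from group-level normals on the unconstrained scale and constrained by the
probit transform.  The default regimes (constrained-scale means; raw sd
0.3) are HC-like a_rew 0.35, a_pun 0.25, beta 3.0 versus AUDP-like a_rew
0.30, a_pun 0.45, beta 2.0 — values chosen once as a plausible regime whose
qualitative pattern matches the clinical phenomenon of interest (faster
punishment learning, slightly slower reward learning, less consistent
choice), since group-level posterior means are not available to copy.
Ground-truth parameters and per-subject schedules are always returned and
persisted next to the data.

What the generator does *not* emulate: response times, within-session
fatigue or attention drift, clinical covariates coupled to behavior, and
model misspecification (subjects are exact RP or EWA agents).  Passing
tests therefore demonstrate that the pipeline is correct and well
calibrated under its own generative assumptions, not that the models
capture human choice.

## Problem sizes and numerical choices

Tests and the acceptance script use scaled-down sampler settings chosen as
reasonable desk-scale configurations: convergence check at 2,000 samples
(500 warmup) x 4 chains on a 10-subject, 1-block cohort; recovery at 800
samples x 2 chains on a 28-subject cohort with 200 predictive draws;
replicated group-difference studies at 650 samples, single chain, full
55-subject design, 10 replicates; model selection at 500 samples on
12-subject cohorts.  Posterior-difference HDIs need only a few hundred
draws for the effect sizes the default regimes produce.

Numerical details: softmax log-probabilities use log1p-based stable forms;
NUTS divergences are declared at an energy error of 1,000; the dual
averaging restarts after each metric-window update; HDI requires >= 100
samples; LOOIC requires every unit to have at least one finite
log-likelihood value; model-comparison tables refuse fits whose data hashes
differ and break LOOIC ties by model name.  Degenerate inputs are defined
behavior: constant MCMC chains report R-hat 1 by convention, a subject with
no qualifying perseveration sequences reports a missing (NaN) rate, and a
zero-length dataset is rejected everywhere with a clear error.

## Known limitations

* The RP/EWA update equations are reconstructions (see above); a different
  variant (e.g., chosen-only updating) changes fitted values — the flag
  exists, but defaults were fixed before any fitting and are not tuned.
* Mixed-model standard errors come from the numerical Hessian of the
  GH-approximated likelihood; with very small clusters or variance near
  zero they inherit the usual boundary caveats.
* PSIS-LOO with subject-level units can flag high Pareto-k for influential
  subjects in small groups; the diagnostics are reported, not suppressed.
* Single-chain configurations used in some replicated tests trade R-hat
  diagnosability for runtime; the convergence criterion itself always runs
  at 4 chains.
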