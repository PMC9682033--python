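# Methods

## The paradigm

Two probabilistic selection tasks are interleaved trial by trial. In each
trial one stimulus pair is shown and the agent picks one option; the better
option of a pair yields positive feedback with probability *p* and the worse
option yields negative feedback with the same *p*. The **inducer** task's
*p* is manipulated blockwise — low 7/12, medium 9/12, high 11/12 — while the
**reference** task always runs at 9/12. A session is one training block plus
15 experiment-proper blocks of 24 trials (12 per task, fresh stimulus pair
per task per block, 32 pairs in total). The inducer manipulation controls the
average reward rate (ARR) experienced across both tasks; the reference task
measures whether that rate transfers into learning performance on an
independent task.

Design constraints enforced by construction and checked by
`validate_session`: every consecutive block triplet contains each condition
once (five blocks per condition); within a block no task repeats more than
three times in a row; outcome schedules are **fixed-ratio** — exactly *k* of
the better option's 12 pre-drawn outcomes are positive (and exactly *k* of
the worse option's are negative), independently shuffled per option. The
fixed-ratio choice (rather than i.i.d. Bernoulli draws) reflects the design's
exact-twelfths probabilities and makes realized reward rates independent of
the agent's choices; outcomes are pre-assigned per trial and option, so a
simulation and a likelihood evaluation see identical feedback for identical
choices. Three feedback-magnitude schemes are provided: ±1 everywhere
(experiment 1); reference ±1 with inducer ±3.0 / ±1 / ±0.6 for low/medium/
high (experiment 2 — equalizing expected points at 0.5/trial for an
always-correct agent, verified by `expected_points_per_trial`); +1/0
(experiment 3). Timeouts are recorded as missed trials at −2 points.

The training block's condition is not specified by the design source; it is
fixed at medium (the neutral point) and excluded from all fitting and
statistics. Trial indices are 1-based; "late trials" means within-task
indices 9–12.

## The model family

All nine models are delta-rule (Q-learning) learners with a softmax policy

    Q_i <- Q_i + alpha * delta,    delta = R - Q_i,
    P(better) = 1 / (1 + exp(-beta * (Q_better - Q_worse))).

Three null models treat the tasks as independent:

- `null-a` — one learning rate alpha, decision weight beta (2 parameters);
- `null-aPE` — separate rates for positive/negative delta (3);
- `null-aR` — two-stream model tracking positive and negative outcomes
  separately, `Q_pos <- lambda_pos*Q_pos + alpha*(w_pos*R_pos - Q_pos)` and
  analogously for the negative stream, deciding on `Q_pos + Q_neg` (6).
  Because only one feedback is delivered per trial, the other stream's R is
  set to 0 and **both** streams of the chosen option update every trial; with
  lambda = w = 1 the two streams sum telescopically and the model reduces
  exactly to `null-a` (a property the tests assert).

Six ARR models add a single scalar accumulator `mu`, shared across both tasks
and updated once per non-missed trial of either task, either from prediction
errors (`*-PE`: `mu <- mu + alpha_mu*(delta - mu)`) or from rewards (`*-R`:
`mu <- mu + alpha_mu*(R - mu)`). `mu` modulates one of three targets:
the prediction error itself (`FB-*`: `delta = R - Q + mu`), the learning
rate (`a-*`: `alpha(t) = clip(alpha_0*(1+mu), 0, 1)`), or the decision
weight (`b-*`: `beta(t) = max(0, beta_0*(1+mu))`). The shared accumulator is
the only channel through which the inducer condition can influence reference
learning.

Conventions fixed here (the design source is silent on them):

- Q and mu initialize at 0, so modulated models start at their constant terms
  alpha_0 / beta_0 when the average reward is zero.
- `mu` **resets at each block boundary**: conditions are blockwise, and
  carrying `mu` across blocks would bleed one condition into the next. The
  alternative (carry-over) is a genuine open choice; resetting keeps the
  per-block ARR trajectories condition-pure.
- Within a trial: delta is computed with the pre-update mu, the chosen
  option's Q updates, then mu updates. For `FB-PE` the mu update consumes the
  same mu-augmented delta used for learning (the delta that actually drives
  behavior).
- The clip/floor on modulated alpha and beta guards the ±3-point scheme,
  where |mu| can exceed 1.
- Missed trials contribute no likelihood and no state update (including mu);
  the sign split in `null-aPE` is on delta, not on the feedback's valence
  label (relevant where "negative" feedback is 0 points).

Nesting: with `alpha_mu = 0` every ARR model is likelihood-identical to
`null-a`, as is `null-aPE` with equal rates — asserted exactly in the tests,
which also check the full likelihood against an independent straight-line
per-trial oracle at 1e-10.

The likelihood/trajectory inner loop is compiled with numba; `-log P(chosen)`
is evaluated as `log1p(exp(-x))` for numerical exactness at large decision
weights.

## Hierarchical fitting and model comparison

The package implements an empirical-Bayes EM with random effects over both
parameters and model identity:

- Parameters are fit in an unconstrained space (sigmoid for unit-interval
  parameters, exp for nonnegative weights; round-trip exact to 1e-10).
- E-step: per subject and model, MAP estimation under the current Gaussian
  group prior (L-BFGS with numerical gradients; 10 prior-drawn restarts on
  the first pass, warm starts plus one fresh draw thereafter), Laplace
  log-evidence `logpost(MAP) + (d/2)log(2pi) - 0.5*logdet H` with a
  finite-difference Hessian (ridge-regularized if not positive definite);
  responsibilities proportional to frequency x exp(evidence).
- M-step: responsibility-weighted group means and variances (MAP spread plus
  per-subject posterior variance, floored at 0.01); Dirichlet concentration
  1 + summed responsibilities. Iterate to max-change < 1e-4 or 50 iterations.
- Initial priors: mean 0, variance 6.25 in unconstrained space (weakly
  informative); Dirichlet prior 1 per model.

Exceedance probabilities (EP) are Monte-Carlo fractions of Dirichlet draws
(default 1e5, seeded) in which a model's frequency is maximal. The Bayes
omnibus risk (BOR) — the posterior probability that all models are equally
frequent — compares the variational free energy of the free-frequency model
(the standard Dirichlet lower bound: weighted evidences + E[log r] terms +
assignment entropy − KL of the Dirichlet posterior from its prior) against
the exact evidence of the uniform-frequency null; this analytic route is
deterministic, so the Monte-Carlo budget is spent on EP only. Protected
exceedance probabilities follow as `PXP = EP*(1-BOR) + BOR/K`.

## The synthetic cohort

The study's raw choice data are not deposited, so cohorts are emulated: each
synthetic participant receives a fresh session realization and choices
forward-simulated from a family model, with generating parameters recorded.
The default cohort mirrors the included sample (n = 148, split 50/58/40
across the three magnitude schemes) and generates from the
reward-accumulating, delta-modulating model (`FB-R`), the family member the
comparison machinery selects on such data.

Default generating parameters are `alpha = 0.4`, `beta = 2.5`,
`alpha_mu = 0.7`, calibrated once so the simulated cohort matches the printed
group-level behavior of the study — grand-mean late hit rate about 0.79–0.81
and a low-minus-medium reference difference about −0.04 (within the reported
confidence interval), yielding the qualitative pattern low < medium ≈ high.
Parameter-recovery simulations draw uniformly from alpha in [0.05, 0.6],
alpha_mu in [0.05, 0.7], beta in [1, 10] (and, for the wider family,
discounts in [0.5, 1], outcome weights in [0.5, 2]) — a plausible span of
fitted values, fixed once.

What the generator does **not** emulate: reaction times and timeouts (agents
never miss unless a missed-trial rate is injected); session-position or
fatigue effects; between-subject parameter heterogeneity in the default
(fixed-parameter) cohort; and the per-experiment breakdown of the transfer
effect — at the calibrated defaults the effect is carried mainly by the ±1
and ±3 magnitude schemes while the +1/0 scheme is near-null, whereas the
study observed it in each experiment separately. Passing tests therefore
demonstrate that the pipeline detects and attributes the transfer mechanism
when it is present, not that these parameter values describe human players.

Exclusion rules (exact thresholds unit-tested at their boundaries): pooled
late hit rate (< 0.6 excludes, computed over within-task trials 9–12 of all
30 task-blocks, non-missed trials only), missed trials (> 20 excludes), and
more than two maximal runs of > 10 consecutive same-side presses (sides are
randomized per trial in synthetic sessions; a missed trial breaks a run).
The "last four trials" pooling across tasks and blocks is one reading of the
protocol; it matches the late-trial learning-performance definition used in
the analyses.

## Statistics

Learning performance is the non-missed hit rate over within-task trials 9–12
per subject, condition and task. The group analysis is a split-plot ANOVA
(between: experiment; within: condition), computed by `pingouin.mixed_anova`
and cross-checked in the tests against a brute-force sums-of-squares oracle;
its type-I error is calibration-tested at the nominal 5% under a null
simulation. Pairwise condition contrasts are paired two-tailed t-tests with
95% CIs and Cohen's d = mean(diff)/SD(diff) (consistent with d ~ t/sqrt(n)).
Model-fitted hit rates average the fitted P(better) over the observed late
trials — a deterministic, lower-variance analogue of re-simulating choices —
and actual-vs-fitted agreement is summarized by Pearson correlations of the
overall means and of each pairwise condition difference.

## Problem sizes

The shipped analyses use reduced sizes chosen as the package's default
desk-scale configuration: parameter recovery at 200 virtual participants
(the study's own recovery used 1,000; `arrlearn recover --n 1000` reproduces
that scale), model recovery at 40 agents per replicate with EM capped at 15
iterations (the winner stabilizes within a few iterations; the library
default remains 50), and the behavioral-effect cohort at the study's n = 148.

## Known limitations

- The EM treats group posteriors diagonally; parameter covariances are not
  estimated, and evidence is Laplace-approximated rather than sampled.
- BOR uses a variational bound for the alternative's evidence; it is slightly
  conservative (favoring the null) in small cohorts.
- With blockwise mu resets, the first trials of each block carry no ARR
  information; a carry-over variant would need a design with randomized
  block lengths to be identifiable.
- The two-stream model's both-streams-update convention is one resolution of
  an ambiguity in the original formulation; the neutral-parameter reduction
  to the canonical model holds under this convention.
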