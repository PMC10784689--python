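# Methods

This note documents the statistical model behind `physbattery`, the
design choices that were genuinely open, the numerical conventions, and
what the synthetic-data tests do and do not establish about real data.

## The generative model

A battery of binary-choice tasks is simulated from a guessing-floor
latent-trait model. Subject *i* carries a general ability
θᵢ ~ N(0, 1) and, per task *t*, an independent task-specific ability
s_{it} ~ N(0, 1). Trial *j* of task *t* is answered correctly with
probability

    P = c_t + (1 − c_t) · logistic( a_t · (λ_t θᵢ + √(1 − λ_t²) s_{it} − b_j) )

with chance floor c_t (0.5 for two-alternative tasks), discrimination
a_t ≥ 0, shared-factor loading λ_t ∈ [0, 1], and item difficulties
b_j ~ N(0, σ_b²). The loading parameterization fixes the *stable*
ability variance at 1, split λ_t² : (1 − λ_t²) between common and
task-specific parts. Trials are conditionally independent given the
latents; missingness is completely at random at a configurable rate.
A logistic (not probit) link is used — the standard three-parameter
convention, with closed-form checks (at a_t = 0, P = c + (1−c)/2
exactly).

Covariate tasks (mental rotation, working memory, face memory) are
linear in θ and a second "spatial" latent correlated ρ with θ by
Cholesky mixing, plus Gaussian noise, then standardized. One shared
spatial nuisance latent is the minimal structure that makes
residualization tests meaningful.

### Defaults

The default roster mirrors a five-task physical-reasoning battery:
48, 64, 240, 40 and 58 trials, all at chance 0.5. Remaining defaults
were fixed once as plausible study conditions: loadings
0.60/0.65/0.30/0.70/0.60 (the collision mass-inference task gets a
deliberately low common loading — its reliable variance is dominated by
a task-specific perceptual bias, producing the dissociation pattern the
analyses must detect), discrimination a = 1.5, σ_b = 1 (no empirical
item-difficulty spread is available, so σ_b is exposed in config rather
than asserted), ρ = 0.3, missing rate 0.02, n = 300 subjects. An
`ability_sd` multiplier on θ and s (default 1) produces null batteries
with no subject-level variance for calibration studies.

Randomness flows from one master seed through `SeedSequence` spawn keys
indexed by purpose and position, so adding a task or covariate never
perturbs draws for earlier ones, and two functions given the same seed
use identical split streams (this is what makes the
factor-to-reliability ratio a paired comparison; see below).

Stimulus-design helpers enumerate full factorial crossings (e.g.
14 objects × 4 ramp angles × 4 surface materials = 224 stay-or-go
stimuli; 30 ordered pairs of six ball weights × 2 filmings × 4
presentations = 240 collision trials) and produce 50/50-balanced binary
ground-truth outcome sets for knock-off style designs.

## Split-half reliability

Per iteration, each task's trials are split uniformly at random into
balanced halves — one joint split per iteration across all tasks, which
is required for the combined measure and the factor validation to see
consistent halves. Subjects are scored per half (proportion correct
over non-missing trials; a cell with no observed trials is NaN and
drops out pairwise), half scores are correlated across subjects, and
the Fisher z is recorded. The estimate is the mean z over iterations
with a 2.5/97.5-percentile interval of the iterated z distribution.
Iterations with a zero-variance half are flagged and excluded (more
than 50% degenerate is a hard error): rare all-correct halves do occur
in small fixtures, and failing the whole run would be worse than
excluding and reporting the count. No test-length (prophecy) correction
is applied — the split-half value is a conservative reliability
estimate, and is reported as such.

### The permutation test

The significance of a split-half correlation is assessed by breaking
the subject correspondence between halves. Two naive constructions are
miscalibrated, which matters when the test is run on data without the
luxury of enormous effects:

* Comparing the *mean* z over many splits against a null of
  *single-split* shuffled z values is strongly conservative — single
  draws have far more variance than a mean.
* Comparing the mean against shuffled-alignment *means* over the same
  splits is anticonservative (≈12% rejections at α = 0.05 in our
  measurements): with balanced halves, half-B = 2·(overall mean) −
  half-A identically, so the observed mean z carries a shared
  across-split component (the subject totals) that no alignment shuffle
  of derived half scores can reproduce.

The implemented p is therefore an **exact conditional test on one
dedicated inference split** (drawn from its own seed stream):
conditional on that split's half scores, each of the `n_perm` null
draws shuffles the subject alignment of half B, and
`p = (1 + #{null ≥ observed}) / (1 + n_perm)` (one-sided: positive
association is the hypothesis). Under the
no-individual-differences null the observed and permuted statistics
are exactly exchangeable, so the test is calibrated by construction —
empirically 5–6% rejections at α = 0.05 over 500 null batteries. The
iterated mean z and its CI remain the reliability estimate; if the
inference split is degenerate it is redrawn (up to 50 attempts). The
same construction is used for the factor-validation and residual
permutation tests.

Between-task correlations use pairwise deletion over subjects (matching
the per-task exclusion policy, which removes a subject from a single
task's analyses when more than 25% of that task's trials are missing,
while keeping them elsewhere) and 95% percentile bootstrap CIs over
subject resamples. The resampling unit for these CIs is the subject;
resampling splits instead would measure split noise, which the
within-task cells already summarise. BCa intervals are out of scope.
The difference between two dependent correlations is tested by jointly
resampling subjects, recording Δz per replicate, and doubling the
smaller tail (add-one corrected, capped at 1).

## Single-factor model and cross-validated validation

Factor extraction is iterated principal-axis factoring on the task
Pearson correlation matrix: initial communalities from squared multiple
correlations, leading eigenpair of the reduced matrix, iterate until
the largest communality change is below 1e−6 (cap 1000; non-convergence
returns a flagged result with a warning rather than failing — on null
data there is no factor to converge to). Communalities above 1
(Heywood cases) are clamped to 0.9999 and flagged. Loadings are
sign-oriented so their sum is nonnegative. Subject scores use the
regression (Thurstone) method `f = Z R⁻¹ λ` on column-standardized
accuracies (undefined cells mean-imputed for scoring only) and are
standardized. The extraction method is not pinned down by the problem;
principal-axis was chosen for robustness with five variables at modest
n, and a one-factor maximum-likelihood fit (profile over uniquenesses)
is available behind `method="ml"`. Whether input accuracies are
standardized before fitting is moot: the fit operates on the
correlation matrix.

The cross-validated analysis repeats, per iteration: split all tasks'
trials; fit the factor on half-A accuracies; correlate its scores with
each task's half-B accuracy (Fisher z). `ratio_to_reliability` divides
`tanh(mean z_factor)²` by `tanh(mean z_split-half)²` computed **on the
identical splits** — pairing the two quantities removes split noise
from the comparison. Interpretation caveats, visible in synthetic
ground truth:

* The ratio's ceiling behavior depends on the share of stable variance
  that is common. Under the generative model the ratio approaches
  λ²·(1 + noise share) for an ideal factor; with λ < 1 a correct
  implementation sits *below* 1 by the task-specific share, and at
  λ = 1 it sits slightly *above* 1 because the denominator's halves are
  both noisy while the factor is averaged over tasks. Empirical ratios
  near 1 therefore indicate that a battery's stable variance is almost
  entirely common — they are not a generic property of any reliable
  battery.
* Splits operate on trials as given; any repeated-presentation
  structure within a task is not collapsed before splitting.

## Residualization

`ols_residuals` is ordinary least squares with an intercept (fit via
statsmodels); covariates are standardized internally, making reported
coefficients comparable and the analysis invariant to affine rescaling
of covariate scores. The residual split-half analysis regresses each
half's combined score on the covariates within each iteration and
correlates the two residual vectors; residuals are orthogonal to every
covariate column by construction. The cross-measure mode
(`residual_correlation`) partials the same covariates out of two
different score vectors (e.g. a short-form battery and a novel transfer
task) and correlates the residuals across measures — the same
operation applied to two measures rather than two halves.

One caveat the synthetic ground truth exposes: accuracy is a
*logistic*, not linear, function of ability, so when a covariate
measures the generative latent perfectly, linear residualization
removes the linear component but leaves a small stable nonlinear
remnant (residual z ≈ 0.1 at λ = 1 with the default roster). This is a
property of regressing a bounded score on an unbounded latent, not an
implementation artifact.

## Battery compression

`compress_battery` is pure random search: subjects are split once into
selection and validation sets (default 50% holdout); each candidate
draws k trials per task; candidates are scored by the correlation
between subset mean accuracy and full-battery mean accuracy on the
selection subjects; the argmax (first-seen tie-break) is re-scored on
the validation subjects. Conventions, each with the alternative
available behind a flag:

* **Part-whole overlap.** The subset's trials are included in the
  full-battery comparison score — faithful to the procedure the method
  reproduces, but optimistically biased; `comparison="exclude"` drops
  the selected trials from the comparison for an unbiased diagnostic.
* **Battery score.** Mean-of-task-means (each task weighted equally,
  matching the combined reliability measure) rather than a grand mean
  over trials weighted by trial count; `grand_mean=True` switches.
* **Cross-validation unit.** A single subject-level holdout; setting
  `holdout_fraction=0` reproduces selection-only search with no
  validation, and neither mode's correlation is asserted to be the
  published in-sample figure, since the published procedure's subject
  reuse is unspecified.

With a fixed seed the candidate stream is a prefix sequence, so the
train correlation is nondecreasing in the iteration budget; an
exhaustive mode enumerates all k-subsets when feasible and is tested
against brute-force enumeration.

## Exclusion rules

Whole-subject rules: below chance on two or more tasks (strict `<` by
default; the boundary convention is configurable since it is not pinned
down), working-memory symmetry accuracy below 0.85, a zero
working-memory span score, and a same-response-on-every-trial bot
filter. The bot filter uses the raw response stream when a `response`
column is present; otherwise it falls back to exact equality of every
observed task accuracy with the task's constant-response accuracy
(defaulting to chance) — the filter targets bots, not low scorers.
Missingness is per-task: a subject missing more than 25% of a task's
trials is dropped from that task only and retained elsewhere.
Exclusions are idempotent and every trigger is reported as
`{subject_id, rule, detail}`.

## Problem sizes and determinism

Default analysis sizes in the test suite and acceptance script —
100–400 subjects, 30–500 split iterations, 200–500 permutations or
bootstrap draws, 500 replicate batteries for calibration — were chosen
as the smallest sizes at which the Monte-Carlo error of each check is
comfortably below its decision threshold. All engines accept the
10,000-iteration settings used at full scale. Everything is
reproducible: one explicit seed per entry point, no wall-clock seeding,
and the pipeline's JSON report is byte-identical across runs of the
same configuration and seed.

## What the synthetic tests do and do not show

The generator reproduces the statistical *structure* the analyses
assume — a shared latent with per-task loadings, task-specific stable
variance, item difficulty spread, guessing floors, trial-level
Bernoulli noise, MCAR missingness, covariates with tunable shared
variance — and the tests verify parameter recovery, calibration and
known closed forms under that structure. Real data differ in ways the
generator does not emulate: learning and fatigue across trials,
response-time structure, non-ignorable missingness, item-by-subject
interactions, and perceptual biases that are correlated across tasks.
Passing tests establish that the *procedures* are correct and
calibrated, not that any particular empirical battery satisfies the
model's assumptions.
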