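# Methods

## The behavioral paradigm being modelled

The package targets case-control studies of metacognition built on three
randomly interleaved yes/no tasks — visual detection, familiarity
("already seen?") and recollection ("blue context?") — each trial followed
by a continuous confidence rating (0 = sure incorrect, 100 = sure
correct).  Stimulus strength takes five levels per task: strength 0 tags
trials whose correct answer is "no" (catch trial, new face, re-paired
context; 20% of trials), strengths 1–4 index increasing evidence (contrast
for detection, encoding lag for the memory tasks).  A session holds 10
blocks of 30 trials, 100 per task, 20 per task × strength cell.  A
calibration session measures memory performance at the four lags and picks
four detection contrasts matching those hit rates, so first-order
performance is equated across tasks within each participant.

## Generative observer model

Each observer is an equal-variance SDT observer.  On a strength-s trial
the decision evidence is x ~ N(μ_s, 1) (μ_0 is the "foil" mean of
strength-0 trials; >0 produces elevated false alarms); the response is
"yes" iff x > c.  Confidence is built from a second evidence variable

    z = (1 − α)·x + α·x₂ + ε,    x₂ ~ N(μ_s, 1),   ε ~ N(0, σ_c²),

where σ_c ≥ 0 is **confidence (metacognitive) noise** and α ∈ [0, 1] the
**confidence boost** — the weight on an independent second stimulus sample,
i.e., information entering confidence beyond the decision sample.  The
rating is the observer's own posterior probability of being correct,
100·P(correct | z, response), computed under a veridical internal model
(the observer knows its μ, c, σ_c, α and the 0.2/0.2/0.2/0.2/0.2 design
priors).  Key consequences, each covered by tests:

- with σ_c = 0, α = 0 the rating is the true posterior, so accuracy within
  a confidence band equals the band (calibration);
- the rating is monotone in z — nondecreasing for "yes", nonincreasing for
  "no";
- behavior is invariant to a common shift of all class means and the
  criterion, which is why only differences μ_s − c are identifiable from
  data.

Evidence variance is fixed at 1 and difficulty is manipulated through μ
alone; the memory tasks share the detection generative form, with lag
mapping directly to μ.  Encoding dynamics, stimulus rendering and response
times are not modelled.

## Synthetic cohorts: what the defaults encode

`default_cohort_config()` encodes the study conditions the package is
exercised under: 36 controls vs 34 patients, 300 trials each.  Control
evidence means (1.23, 1.51, 1.88, 2.25) and criterion 0.84 put hit rates
at ≈65/75/85/92% over strengths and the false-alarm rate at 20% — the
operating range the performance-matched paradigm is designed to produce.
Patients carry an additive first-order deficit mu_shift = −0.3 (hits
80→71%) and a recollection foil shift +0.6 over the control foil 0.25
(false recognitions 28→50%), but identical confidence noise and boost
(σ_c = 1.0, α = 0.2): degraded task performance with intact metacognition.
Between-subject SDs (μ offset 0.3, criterion 0.25, σ_c 0.25 truncated at
0, α 0.08 clipped to [0, 1], foil 0.15 truncated at 0) give realistic
subject heterogeneity without producing chance-level or ceiling observers
in bulk.  What the generator deliberately does not emulate: sequential
/ learning effects, lapses and response biases drifting over blocks,
integer-rounded slider use, and any coupling between confidence and
response time.  Tests passing on these cohorts therefore demonstrate
estimator correctness under the model, not robustness to such real-data
features.

## Type-1 fitting

Per subject × task the model has parameters (μ_1..μ_4, c) with μ
nondecreasing and the strength-0 mean fixed at 0 — a location convention:
yes/no data identify only μ_s − c, and the whole confidence model is
shift-invariant, so a free foil mean would be redundant.  The ML solution
is closed-form: per-cell yes rates with an add-½ adjustment (boundary
cells flagged), ordered by pool-adjacent-violators (the exact
order-constrained binomial MLE), then mapped through the probit.  When a
whole population is fitted (`fit_type1_cohort`, used by the efficiency
pipeline), each cell's rate is first shrunk toward a per-strength beta
distribution with cohort-estimated moments: at ~20 trials per cell the
raw-rate noise otherwise propagates into a downward bias of the
confidence-noise estimate and roughly doubles the replicate spread of
efficiency.  The shrinkage weight vanishes as trial counts grow, so the
estimator remains consistent.

## Population confidence-model fitting

One (σ_c, α) pair is fitted per task × group by maximizing the summed
multinomial log-likelihood of binned ratings, each subject contributing
likelihood terms at its own type-1 parameters — the "collapse to one
population after normalizing for task performance" step: first-order
heterogeneity is absorbed subject-wise, metacognition is estimated
population-wise.

Numerics, in order of the pipeline:

- **Bins**: deciles of the pooled empirical confidence distribution,
  endpoints forced to 0 and 100, adjacent bins under 2% mass merged.
- **Bin probabilities are exact.**  (x, z) are jointly Gaussian given the
  class, so P(z ≤ t, response | s) is a bivariate-normal rectangle
  probability, evaluated through Owen's T (machine precision, exact in the
  σ_c → 0 limit where the correlation reaches 1).  Confidence bin edges
  are mapped to z thresholds by bisection on the analytic confidence
  curve (35 iterations; an earlier grid-interpolation scheme left ~0.003
  total-variation error, enough to displace the fit along the flat σ_c
  direction near the ideal corner).
- **Optimization**: bounded Nelder–Mead from 5 starts on (log σ_c, α),
  log-σ_c floor 10⁻³, best start polished at higher resolution.
- **Identifiability limits.**  Information about σ_c near 0 is second
  order, so at session-scale data (100 trials/subject) σ̂_c has an upward
  spread of ~0.1–0.3 even for an ideal population (consistency was
  verified directly: σ̂_c = 0.013 at 2000 trials/subject with known
  type-1 parameters).  At near-chance first-order performance σ_c and α
  become jointly unidentifiable (a likelihood ridge); the matched design
  keeps populations out of that regime.

## Confidence efficiency

Efficiency compares type-2 sensitivities at identical type-1 parameters:

    AUC₂ = P(confidence_correct > confidence_error) (+ ½ ties)
    d₂   = √2 · Φ⁻¹(AUC₂)
    η    = (d₂(σ̂_c, α̂) / d₂(0, 0))²

η = 1 for the ideal confidence observer (identity holds exactly by
construction), decreases with confidence noise, and exceeds 1 when the
boost contributes genuinely new stimulus information.  The boost benefit
is not globally monotone: at σ_c = 0, η rises from 1.0 to ≈1.8 as α grows
to ≈0.5 and declines to ≈1.5 at α = 1 — averaging the decision sample
with an independent second sample is the variance-optimal combination, so
the peak near equal weighting is a real property of the model, not an
artifact.  Tests assert monotonicity on the rising branch.

Both AUC₂ terms are evaluated on a fixed **standardized reference
observer** (class means 0/1.23/1.51/1.88/2.25, criterion 0.84 — the
paradigm's matched operating point).  This makes η a function of
(σ̂_c, α̂) alone, hence exactly invariant to first-order differences
between the populations being compared — the property the measure exists
for.  Evaluating on each population's own type-1 fits (available via
`reference='population'`) retains a residual d′ dependence of about 0.07
in η per 0.8 of evidence shift, which would masquerade as a metacognitive
difference between groups of unequal ability.  AUC₂ is computed by
quadrature: the z-density of each (class, response) cell on a 161-point
grid (criterion inserted so the ideal observer's density step is exact),
pooled into a weighted rank statistic with tie handling.

## Bootstrap

Dispersion of η is quantified by resampling subjects with replacement
(default B = 1000), reusing the cached type-1 fits and full-sample bin
edges.  Because bin probabilities do not depend on resample
multiplicities, the per-subject log-likelihood contributions are
precomputed on a 31 × 21 local grid in (log σ_c, α) around the
full-sample optimum; each resample's refit is then a weighted sum over
that table plus a quadratic peak interpolation.  The resulting bootstrap
distribution was checked against per-resample numerical refits (SDs agree
to < 3%).  Intervals are percentile 95% CIs; group contrasts are
element-wise differences of two bootstrap vectors.  Resamples with fewer
than two distinct subjects are redrawn.

## Metacognitive sensitivity (two-stage)

Confidence is z-scored within subject (all trials), making slopes
invariant to each subject's scale use.  Accuracy is regressed on
standardized confidence per subject × task by penalized logistic
regression (quadratic penalty 0.5 on the slope — finite estimates under
separation; SE from the penalized curvature).  Cell means are contrasted
with a bias-corrected subject-level bootstrap (2000 resamples; paired
over subjects for within-group task contrasts) and a two-sample JZS Bayes
factor at scale 0.7.  This two-stage estimator approximates a joint
Bayesian mixed-effects logistic model — hierarchical shrinkage and crossed
random effects are not implemented; the intervals are bootstrap, not
credible, intervals.  Stimulus strength is not a per-subject covariate by
default (20 trials per cell under-identify it).

## Bayes factors

The two-sample JZS Bayes factor places a Cauchy(0, r) prior on the
standardized effect size (r = 0.7 throughout, following the convention
the reference values were produced under) and integrates the marginal
likelihood over the prior's inverse-gamma mixing variable, mapped to the
unit interval (adaptive quadrature, absolute tolerance 10⁻¹⁰; the
integration error estimate is returned).  The implementation agrees with
an independent one (pingouin) to < 10⁻⁴ relative and with brute-force
Monte-Carlo prior integration to < 1%.  Welch's t is the default for
descriptive group tables (case-control SDs are rarely equal); pooled
Student t is available.

## Psychometric matching

P(yes | contrast) = γ + (1 − γ − λ)·Φ((log C − m)/w).  γ comes from catch
trials with add-one smoothing (so an all-"no" catch block leaves low
targets feasible), λ is fixed at 0.01 (unidentifiable with three contrast
levels), and (m, log w) maximize the binomial likelihood (Nelder–Mead,
three starts).  Inversion is closed-form, so the round trip reproduces
targets to 10⁻⁹; matching inverts the curve at the four memory hit rates.

## Problem sizes used by the tests and the acceptance script

Statistical checks run at the sizes they state: parameter recovery on 20
cohorts of 30 subjects × 100 trials; first-order invariance on 20
replicate pairs of 30-subject groups separated by ±0.4 in every evidence
mean (B = 1000, shared bin edges); planted-deficit detection on 20 cohorts
of 35 + 35 subjects; the analytic-vs-simulation check on a 20-point
random parameter grid with 10⁶ trials per point; slope null calibration
on 100 subjects.  The contrast CI's measured per-replicate coverage under
these conditions is ≈90%, slightly under nominal — the usual behavior of
percentile cluster bootstraps at a few dozen clusters — which is why
efficiency contrasts should be read together with their point estimates.  `scripts/acceptance.py` recomputes the same
quantities with 5 replicates per block and one default-B (1000) bootstrap;
these replicate counts are the package's reporting choice and are recorded
in the output's `n` fields.

## Known limitations

- η inherits the upward small-sample spread of σ̂_c near the ideal corner;
  population-level contrasts are unaffected (both groups share the bias)
  but absolute η values near 1 should be read with the bootstrap CI, not
  alone.
- The estimator presumes the generative family is correct; miscalibrated
  internal models (over/underconfidence biases that are not noise) are
  absorbed into (σ_c, α) rather than identified separately.
- Exclusion thresholds (ceiling accuracy 0.95, minimum 5 error trials per
  task) are configurable operationalizations of the usual
  preregistration-style criteria, not any particular protocol's exact
  rules.
- The 2×2 χ² and t engines assume independent groups; no corrections for
  multiple comparisons are applied anywhere, matching the reporting style
  of the tables the package emulates.
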