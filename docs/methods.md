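# Methods

This note documents the models, estimators and numerical conventions
implemented in `posbias`, the assumptions behind the synthetic-cohort
generator, and the design choices made where the design was genuinely open.

## Behavioural scoring (FERT)

A session is a 250-trial table: 6 emotions × 10 morph intensities × 4
actors plus 10 neutral faces, in four blocks of 62/62/63/63 trials.
Scoring is trial-order invariant and operates on the 7×7 confusion matrix
of true × chosen emotion plus the per-trial reaction times.

Per emotion we compute the hit fraction, the **unbiased hit rate**
(hit fraction × label precision, the signal-detection correction for
response bias in categorisation tasks; defined as 0 when the label was
never used, since the numerator is then necessarily 0, and flagged),
the **median RT over correct trials only** (midpoint convention for even
counts), **efficiency** = UBH / median RT, and the **misclassification
count** = how often the emotion's label was chosen incorrectly (column sum
minus diagonal).

The four bias scores are log-ratios of valence aggregates, each signed so
that larger = more positive bias. Aggregation is the arithmetic mean of
per-emotion values within each valence, except misclassification, which
pools event counts. Conventions:

* positive = {happy, surprise}, negative = {fear, sadness, anger, disgust};
  neutral belongs to neither valence. Misclassifications *as neutral* are
  excluded from both pooled sums; errors on neutral-face trials count when
  an emotional label was chosen.
* scores are computed as `log(numerator) − log(denominator)` rather than
  `log(ratio)`, so exchanging the valence sets negates every score at the
  bit level — a property the test suite checks exactly.
* if either pooled misclassification sum is 0, 0.5 is added to both
  (Haldane-style continuity correction) and the score is flagged rather
  than dropped.
* trials without a response are excluded from all counts and flagged; a
  metric whose preconditions fail (e.g. no correct trial for an emotion)
  is marked invalid and its session delta is treated as missing.

## Clinical outcomes

Improvement = HAM-D(week 0) − HAM-D(week 4); a positive value is symptom
reduction. Response = reduction of at least 50% of baseline (exactly 50%
counts). A missing week-4 score is imputed by least-squares fitting of
`r(t) = A(1 − e^{−kt})`, A, k ≥ 0, to the observed reductions
r(t) = s(0) − s(t) at weeks 0–3 (multi-start over k; the two-parameter
family is the simplest decay consistent with r(0) = 0), predicting r(4).
A flat series yields the A = 0 solution; on optimiser failure the last
observation is carried forward and flagged. The fit report records Â, k̂
and the residual sum of squares.

## Group statistics

**Split-plot ANOVA.** Each within-subject stratum (Time; Emotion;
Emotion × Time) is projected out per subject with orthonormal contrasts
and analysed as a one-way ANOVA over the between-subject response classes,
yielding the classical sphericity-assumed univariate F tests with
sequential sums of squares. This reproduces R's
`aov(... + Error(subject/(emotion*time)))` exactly (validated, values
frozen in the test suite) and pingouin's `mixed_anova` in the two-level
case. With two sessions the Time × Response F equals the squared pooled
t of the class comparison of change scores — an identity the tests check
to machine precision. Denominator df are computed from complete cases.
Sums of squares more than 24 orders of magnitude below the data's scale
are snapped to zero so degenerate inputs (all-zero change scores) return
F = 0 rather than 0/0.

**Regressions.** The logistic model of response on one bias-change
regressor plus five control covariates (baseline HAM-D, age, gender as a
binary female indicator, psychoactive medication, number of iTBS sessions)
is fitted by Newton–Raphson maximum likelihood; on (quasi-)separation —
plausible at n ≈ 49 — it falls back to Firth's bias-reduced likelihood
with step-halving, flagged in the result. Both the raw odds ratio
exp(β) and the per-SD odds ratio exp(β·SD(x)) are reported, because the
regressor's log-ratio scale makes the raw OR hard to compare across
metrics. Covariates that are constant in a given sample are dropped with
a flag. The linear model of improvement uses OLS with the same covariates;
a rank-deficient design raises an error naming the collinear columns.

**Effect sizes and multiplicity.** Cohen's d uses the pooled SD and a
noncentral-t CI (small-sample convention; the inversion treats extreme-tail
CDF underflow as 0/1). Bonferroni correction uses m = 4 (the four bias
metrics). Baseline tables use Welch t for continuous and Fisher exact for
binary variables.

## GLM / PPI engine

The engine targets desk-scale synthetic volumes; it does no registration,
smoothing or slice timing, and masks must share the data grid.

* **HRF**: gamma density parameterised by mean lag 6 s and dispersion
  (SD) 3 s (configurable), truncated at 32 s and normalised to sum 1 so a
  sustained unit boxcar plateaus at 1.
* **First level**: stimulus functions sampled at 0.1 s, convolved and
  down-sampled at the TR; 11 columns — happy, fearful, their raw
  first-difference temporal derivatives, 6 motion regressors, intercept.
  Fixation carries no regressor (implicit baseline), so "> fixation"
  contrasts are the task betas. Estimation is voxelwise OLS with no
  autocorrelation prewhitening: the generator produces white noise, and
  the engine's inferences are permutation-based at the group level where
  exchangeability, not autocorrelation, is the relevant assumption.
  A helper re-signs maps so an increase in de-activation ("negative BOLD
  response") is reported as positive, tagged in the map's metadata.
* **PPI**: the seed timecourse is the mask mean; interaction regressors
  are products of the *zero-centred* convolved task regressors with the
  seed series (centring for identifiability); the contrast of interest is
  (happy × seed) − (fearful × seed).
* **Second level**: fixed-effects session change (week 2 − baseline) of
  contrast estimates.
* **Third level**: OLS across participants of the change maps on HAM-D
  improvement plus the five control covariates, all de-meaned.
  Family-wise error is controlled by **Freedman–Lane max-T permutation**:
  residuals of the covariates-only model are permuted, the full model is
  refitted, and each voxel's observed |t| is referred to the permutation
  distribution of the image-wide maximum; corrected
  p = (1 + #{maxT ≥ |t|}) / (n_perm + 1). ROI small-volume tests run the
  same machinery inside each mask at α = 0.05/6 (six a-priori regions).
  Cluster-enhancement methods are out of scope; max-T keeps exact FWE
  semantics and is fully testable at this scale.

## Elastic-net model comparison

Two models of HAM-D improvement are compared: clinical (early HAM-D
change at week 2, baseline HAM-D, age, gender, medication) and clinical +
bias-change features. Out-of-sample R² comes from nested cross-validation
(default 5 outer × 5 inner folds, penalty grid of 20 α values ×
l1-ratios {0.1, 0.5, 0.9}); features are standardised with outer-training
statistics only, and both models are always scored on identical outer
folds (assertable from the report). In-sample fit is compared by Gaussian
AIC/BIC with constants omitted and df adjusted for regularisation:
`df = tr[X_A (X_A'X_A + nα(1−r) I)^{-1} X_A']` on the active set A, which
reduces to |A| in the pure-lasso limit and to the number of predictors at
zero penalty (both limits tested). "Improved prediction" is
operationalised as the paired outer-fold R² difference together with the
AIC/BIC ordering; no formal test is attached to the CV difference.

## Synthetic cohorts: what they emulate, and what they do not

**FERT responses** are drawn from a confusion kernel per true emotion ×
intensity: accuracy rises logistically with morph intensity from near
chance to 0.97 (midpoint 4.5, slope 1.8); 45% of error mass goes to a
confusable partner (fear↔surprise, anger↔disgust, sadness↔neutral,
happy→neutral), the rest spreads uniformly. RTs are log-normal per emotion
(positive emotions slightly faster, σ = 0.3) — positive, right-skewed,
median well defined. The **positivity shift** δ multiplies the error mass
on positive response labels by (1 + δ), compensating proportionally on
negative labels, so accuracy and row sums are untouched: it targets the
response criterion (the misclassification metric) directly. Responders
receive δ = 0.335 at the week-2 session by default, calibrated by a
20,000-session Monte Carlo so the planted standardised between-class
effect on the misclassification-bias change is ≈ 1.3; non-responders
receive δ = 0.

**HAM-D trajectories** follow s(t) = s∞ + (s0 − s∞)e^{−kt} with integer
rounding, clipping to [0, 52], and noise SD 1 point. Responder profiles
draw baseline ≈ N(18.3, 2.8) (inclusion floor 14), week-4 fractional
reduction ≈ N(0.70, 0.06) truncated to [0.60, 0.92], k ∈ [0.5, 1.0]/week;
non-responders ≈ N(17.6, 2.3), reduction N(0.22, 0.08) in [0.02, 0.36],
k ∈ [0.3, 0.8]. The margins keep noise-induced label flips rare (≈ 1%),
so observed labels track the generating class. Covariates mirror the
target trial: 41/49 female, 30/49 medicated, ages N(39, 10) clipped to
18–65, and 7/8/9/10 iTBS sessions before week 2 with probabilities
4/37/4/4 out of 49.

**BOLD runs** place task signal (HRF-convolved block regressors with known
betas) in designated active and seed regions, a smooth AR(1) latent
fluctuation in the seed, and a seed-coupled component in target voxels
whose gain differs during happy blocks (the planted PPI effect), plus
white Gaussian noise; motion is six smoothed low-amplitude random walks.
The grid is small (default 8³) and contains no anatomy, physiological
noise, drift or motion artefacts in image space.

For speed, Monte-Carlo experiments use a batched generator
(`posbias.montecarlo`) that represents each session by multinomial
response counts per stimulus cell — exactly the same distribution as the
trial-level simulator because scoring is trial-order invariant (a
property the tests verify both analytically and empirically).

*What passing tests show*: the estimators are correct and calibrated under
the generating model (categorical confusion responses, exponential mood
decay, white-noise block-design BOLD). They do not show robustness to
real-data features the generator omits: response time-outs and lapses,
learning or fatigue across blocks, non-exponential mood trajectories,
scanner drift and motion-correlated artefacts, or atlas/registration error
in ROI masks.

## Problem sizes and seeds

All randomness flows from explicit integer seeds through `SeedSequence`
spawning; every simulation is bit-reproducible. The standard experiment
sizes are 1,000 cohorts (n = 49, 33/16) for calibration and power, 200
datasets × 500 permutations for FWE calibration, 200 replicates for PPI
recovery, and 500 simulations per model-comparison condition; the
acceptance script exposes these as flags. The model-comparison experiments
plant a bias-feature block whose *observed* partial R² beyond early
symptom change is 0.3 (the latent loading is inflated to undo proxy-
measurement attenuation); at that effect size BIC prefers the augmented
model in ~86–90% of simulations — slightly below the nominal 90% —
while at the partial R² implied by the reference trial's reported
out-of-sample R² pair (0.19 → 0.52, i.e. ≈ 0.41) both AIC and BIC exceed
95%. Both conditions
are reported by the acceptance script.

## Known limitations

* The ANOVA assumes sphericity (no Greenhouse–Geisser correction); with
  two within levels per factor pair this matters only for the six-level
  Emotion factor in the follow-up analysis.
* The permutation engine permutes participants freely (one exchangeability
  block); repeated-measures third-level designs would need restricted
  permutation.
* `pb_rt`'s validity depends on at least one correct trial per emotion;
  at chance-level performance the metric degrades to flagged missingness.
* The elastic-net df adjustment applies the ridge-trace formula on the
  active set; it is exact in the orthogonal case and a standard
  approximation otherwise.
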