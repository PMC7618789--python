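# posbias

Analysis pipeline for **positive emotional bias as a marker of depression
treatment response**, with a synthetic-cohort generator that gives every
stage a known ground truth.

Clinical trials of antidepressant interventions (including TMS protocols
such as iTBS over left DLPFC) increasingly measure whether treatment shifts
emotional information processing towards positive material *early* in
treatment, and whether that shift predicts the clinical outcome at the end
of treatment. `posbias` implements that full analysis chain for studies
combining a facial expression recognition task (FERT), weekly HAM-D
ratings, and a block-design emotional-faces fMRI task:

* **FERT scoring** — four positive-bias metrics per session, each a
  log-ratio for positive ({happy, surprise}) versus negative
  ({fear, sadness, anger, disgust}) emotions, signed so higher = more
  positive bias:

  - unbiased hit rate (signal-detection accuracy:
    `UBH = hit fraction x (times correctly chosen / times chosen)`),
    `pb_ubh = ln(mean UBH_pos) − ln(mean UBH_neg)`;
  - median correct reaction time, `pb_rt = ln(RT_neg) − ln(RT_pos)`;
  - efficiency (`UBH / median RT`), log-ratio positive over negative;
  - misclassification bias — a response-criterion measure:
    `pb_misclass = ln(# errors chosen as positive) − ln(# errors chosen as
    negative)`, counted over erroneous label choices regardless of the true
    emotion.

* **Clinical outcomes** — HAM-D improvement (baseline − week 4), responder
  classification (≥ 50% reduction), and exponential-decay imputation
  `r(t) = A(1 − e^{−kt})` of a missing week-4 score from weeks 0–3.

* **Group statistics** — Time × Clinical Response split-plot ANOVAs per
  metric (with an Emotion × Time × Response follow-up), covariate-adjusted
  logistic and linear regressions (baseline HAM-D, age, gender, medication,
  number of iTBS sessions), Bonferroni correction over the four metrics,
  Cohen's d with noncentral-t CIs, and Welch-t / Fisher-exact baseline
  tables.

* **GLM/PPI engine** — a miniature voxelwise task-fMRI engine: first-level
  GLM (gamma HRF, temporal derivatives, 6 motion regressors, Happy > Fearful
  and constituent contrasts), within-participant session change, seed-based
  psychophysiological interaction (PPI) designs, group GLM on HAM-D
  improvement, and family-wise-error control by Freedman–Lane max-T
  permutation, whole-brain or within six a-priori ROI masks at α = 0.05/6.

* **Model comparison** — elastic-net models of HAM-D improvement ("clinical"
  vs "clinical + bias change"), nested cross-validated R², and AIC/BIC with
  regularisation-adjusted degrees of freedom
  `df = tr[X_A (X_A'X_A + λ₂I)^{-1} X_A']`.

* **Synthetic cohorts** — patient-level data from such trials are usually
  unshareable, so `posbias.synthetic` generates cohorts with the same
  statistical structure: 250-trial FERT sessions (6 emotions × 10
  intensities × 4 actors + 10 neutral) with confusion-structured responses
  and a tunable *positivity shift*, exponential-decay HAM-D trajectories
  with responder/non-responder profiles (default 33/16 at n = 49),
  block-design BOLD (4 happy + 4 fearful + 9 fixation blocks, 120 faces per
  emotion) with known amplitudes and condition-specific seed coupling, and
  realistic covariates.

## Worked example

```python
from posbias.synthetic import CohortSpec, simulate_cohort
from posbias.inference import (analysis_frame_from_cohort, bonferroni,
                               cohens_d, logistic_predict_response,
                               mixed_anova_time_by_response)

cohort = simulate_cohort(CohortSpec(master_seed=42))   # n=49, 33/16 split
frame = analysis_frame_from_cohort(cohort)

anova = mixed_anova_time_by_response(frame, "pb_misclass")
logit = logistic_predict_response(frame, "pb_misclass")
d = cohens_d(frame.loc[frame.response == "responder", "pb_misclass_delta"],
             frame.loc[frame.response == "non-responder", "pb_misclass_delta"])
```

With the default generator (a positivity shift planted in responders'
week-2 session, calibrated to a standardised effect of about 1.3) this
prints, for the misclassification-bias metric:

```
Time x Response: F(1,47) = 15.14, p = 0.0003138  (p_corr = 0.0013, m = 4)
logistic:  beta = 3.71, z = 2.88, p = 0.003969, OR = 40.73 (per SD: 4.10)
Cohen's d = 1.19, 95% CI [0.54, 1.82]
```

i.e. responders show a larger increase in the tendency to label ambiguous
faces as positive, the effect survives covariate adjustment, and the
standardised group difference is close to the planted value.

The same cohort can be pushed through every stage from the shell:

```bash
posbias run-all --seed 42 --out-dir scratch/demo     # writes tables, maps,
                                                     # stats JSON + manifest
posbias score-fert --baseline b.csv --week2 w.csv --out scores.json
posbias permute --maps sub-*.nii --design design.csv --n-perm 1000 \
    --seed 0 --out-dir scratch/perm
```

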