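"""Batched cohort simulation for calibration and power experiments.

The bias scores are invariant to trial order, so a FERT session can be
summarised by multinomial response counts per (true emotion, intensity)
cell together with log-normal reaction-time draws — exactly the
distribution produced by the trial-level simulator in
:mod:`posbias.synthetic`, but two orders of magnitude faster.  This module
uses that representation to run the Monte-Carlo experiments the pipeline's
statistical guarantees rest on:

* type-I error calibration of the Time x Response interaction and of the
  covariate-adjusted logistic bias coefficient under a null cohort
  (identical positivity shift in both response classes);
* recovery of a planted standardised group difference (Cohen's d) in the
  misclassification-bias change, and the power of the logistic test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import (
    EMOTION_INDEX,
    EMOTIONS,
    NEGATIVE_EMOTIONS,
    NON_NEUTRAL,
    N_ACTORS,
    N_INTENSITIES,
    N_NEUTRAL,
    POSITIVE_EMOTIONS,
)
from .fert import METRICS
from .inference import (
    analysis_frame_from_cohort,  # noqa: F401  (re-exported for experiments)
    cohens_d,
    logistic_predict_response,
    mixed_anova_time_by_response,
)
from .synthetic import CohortSpec, ResponseModel, _responder_trajectory

_POS = [EMOTION_INDEX[e] for e in POSITIVE_EMOTIONS]
_NEG = [EMOTION_INDEX[e] for e in NEGATIVE_EMOTIONS]


def _cells(model: ResponseModel) -> tuple[np.ndarray, np.ndarray]:
    """Stimulus cells of one session: counts (61,) and response
    probabilities (61, 7); 60 emotion x intensity cells of 4 trials plus
    one neutral cell of 10."""
    counts, pvals = [], []
    for emo in NON_NEUTRAL:
        ei = EMOTION_INDEX[emo]
        for j in range(N_INTENSITIES):
            counts.append(N_ACTORS)
            pvals.append(model.kernel[ei, j])
    counts.append(N_NEUTRAL)
    pvals.append(model.kernel[EMOTION_INDEX["neutral"], 0])
    return np.asarray(counts), np.asarray(pvals)


def batch_bias_scores(model: ResponseModel, n_sessions: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Bias scores for ``n_sessions`` independent sessions, shape (n, 4)
    with columns ordered as :data:`posbias.fert.METRICS`."""
    counts, pvals = _cells(model)
    draws = rng.multinomial(counts, pvals, size=(n_sessions, len(counts)))
    conf = np.zeros((n_sessions, 7, 7))
    for e in range(6):
        conf[:, e] = draws[:, e * N_INTENSITIES:(e + 1) * N_INTENSITIES].sum(axis=1)
    conf[:, 6] = draws[:, -1]

    diag = conf[:, np.arange(7), np.arange(7)]
    presented = conf.sum(axis=2)
    chosen = conf.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ubh = np.where(chosen > 0, (diag / presented) * (diag / chosen), 0.0)

    # median correct RT: draw per-trial RTs and take the median of the
    # first n_correct draws (iid, so prefix selection is distribution-exact)
    log_med = np.log([model.rt_median_ms[e] for e in EMOTIONS])
    sig = np.array([model.rt_sigma[e] for e in EMOTIONS])
    max_n = 40
    rts = np.exp(rng.normal(log_med[None, :, None], sig[None, :, None],
                            size=(n_sessions, 7, max_n)))
    nc = diag.astype(int)
    masked = np.where(np.arange(max_n)[None, None, :] < nc[:, :, None], rts, np.inf)
    srt = np.sort(masked, axis=2)
    lo = np.take_along_axis(srt, np.maximum((nc - 1) // 2, 0)[:, :, None], axis=2)[:, :, 0]
    hi = np.take_along_axis(srt, np.maximum(nc // 2, 0)[:, :, None], axis=2)[:, :, 0]
    med = np.where(nc > 0, (lo + hi) / 2.0, np.nan)
    with np.errstate(invalid="ignore"):
        eff = ubh / med
    misclass = chosen - diag

    def _lr(num, den):
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.log(num) - np.log(den)

    mis_pos = misclass[:, _POS].sum(axis=1)
    mis_neg = misclass[:, _NEG].sum(axis=1)
    zero = (mis_pos == 0) | (mis_neg == 0)
    mis_pos = np.where(zero, mis_pos + 0.5, mis_pos)
    mis_neg = np.where(zero, mis_neg + 0.5, mis_neg)
    out = np.column_stack([
        _lr(ubh[:, _POS].mean(axis=1), ubh[:, _NEG].mean(axis=1)),
        _lr(med[:, _NEG].mean(axis=1), med[:, _POS].mean(axis=1)),
        _lr(eff[:, _POS].mean(axis=1), eff[:, _NEG].mean(axis=1)),
        _lr(mis_pos, mis_neg),
    ])
    return out


def simulate_analysis_frame(spec: CohortSpec, seed: int | np.random.SeedSequence
                            ) -> pd.DataFrame:
    """One cohort's analysis frame via the batched generator.

    Distribution-identical to ``analysis_frame_from_cohort(simulate_cohort
    (spec))`` (without raw trial tables); used for the Monte-Carlo
    experiments where thousands of cohorts are needed.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    n = spec.n
    n_resp = min(max(int(round(n * spec.responder_fraction)), 1), n - 1)
    is_resp = np.zeros(n, dtype=bool)
    is_resp[:n_resp] = True

    base = ResponseModel.default()
    models = {
        True: base.with_positivity_shift(spec.delta_responder),
        False: base.with_positivity_shift(spec.delta_nonresponder),
    }
    scores1 = batch_bias_scores(base, n, rng)
    scores2 = np.empty_like(scores1)
    scores2[is_resp] = batch_bias_scores(models[True], n_resp, rng)
    scores2[~is_resp] = batch_bias_scores(models[False], n - n_resp, rng)

    # HAM-D trajectories and outcomes
    s0 = np.empty(n)
    s4 = np.empty(n)
    for i in range(n):
        traj = _responder_trajectory(rng, bool(is_resp[i]), spec.hamd_noise_sd)
        vals = traj.expected(np.array([0.0, 4.0])) + rng.normal(0, spec.hamd_noise_sd, 2)
        s0[i], s4[i] = np.clip(np.round(vals), 0, 52)
    improvement = s0 - s4
    responder = improvement / np.maximum(s0, 1e-9) >= 0.5

    frame = pd.DataFrame({
        "participant_id": [f"sub-{i + 1:03d}" for i in range(n)],
        "true_class": np.where(is_resp, "responder", "non-responder"),
        "response": np.where(responder, "responder", "non-responder"),
        "hamd_baseline": s0, "hamd_week4": s4, "hamd_improvement": improvement,
        "responder": responder,
        "age": np.clip(rng.normal(spec.age_mean, spec.age_sd, n), 18, 65),
        "gender_female": (rng.random(n) < spec.p_female).astype(float),
        "medication": (rng.random(n) < spec.p_medication).astype(float),
        "n_itbs_sessions": rng.choice([7, 8, 9, 10], size=n,
                                      p=spec.itbs_session_probs),
    })
    for j, m in enumerate(METRICS):
        frame[f"{m}_baseline"] = scores1[:, j]
        frame[f"{m}_week2"] = scores2[:, j]
        frame[f"{m}_delta"] = scores2[:, j] - scores1[:, j]
    return frame


@dataclass
class CalibrationResult:
    """Rejection rates (and effect summaries) over replicated cohorts."""

    n_cohorts: int
    anova_rejection_rate: float
    logistic_rejection_rate: float
    mean_cohens_d: float
    logistic_power: float  # == logistic_rejection_rate; kept for symmetry

    @property
    def mc_se(self) -> float:
        p = self.anova_rejection_rate
        return float(np.sqrt(p * (1 - p) / self.n_cohorts))


def run_calibration(spec: CohortSpec, n_cohorts: int, seed: int,
                    metric: str = "pb_misclass", alpha: float = 0.05
                    ) -> CalibrationResult:
    """Monte-Carlo rejection rates of the interaction ANOVA and of the
    adjusted logistic bias test, plus the mean estimated Cohen's d of the
    bias change between response classes, over ``n_cohorts`` cohorts.

    With ``delta_responder == delta_nonresponder`` this measures type-I
    error; with a planted shift it measures power and effect recovery.
    """
    ss = np.random.SeedSequence(seed)
    rej_a = rej_l = 0
    ds = []
    for child in ss.spawn(n_cohorts):
        frame = simulate_analysis_frame(spec, child)
        res_a = mixed_anova_time_by_response(frame, metric)
        res_l = logistic_predict_response(frame, metric)
        rej_a += res_a.p < alpha
        rej_l += res_l.p < alpha
        col = f"{metric}_delta"
        x = frame.loc[frame.response == "responder", col]
        y = frame.loc[frame.response == "non-responder", col]
        if len(x) >= 2 and len(y) >= 2:
            ds.append(cohens_d(x, y).effect)
    return CalibrationResult(
        n_cohorts=n_cohorts,
        anova_rejection_rate=rej_a / n_cohorts,
        logistic_rejection_rate=rej_l / n_cohorts,
        mean_cohens_d=float(np.mean(ds)),
        logistic_power=rej_l / n_cohorts,
    )


def model_preference_rates(partial_r2_bias: float, n_sims: int, seed: int,
                           n: int = 49) -> dict[str, float]:
    """Fraction of simulations in which AIC / BIC prefer the augmented
    (clinical + bias) model, with hyperparameters CV-selected per model.

    ``partial_r2_bias > 0`` plants genuine signal in the bias block;
    0 makes the bias features pure noise (the null for criterion-based
    complexity penalties).
    """
    from .model_comparison import aic_bic, select_elastic_net
    from .synthetic import simulate_prediction_features

    ss = np.random.SeedSequence(seed)
    aic_pref = bic_pref = 0
    for child in ss.spawn(n_sims):
        fit_seed = int(child.generate_state(1)[0] % (2**31))
        Xc, Xa, y = simulate_prediction_features(
            n=n, partial_r2_bias=partial_r2_bias, seed=child)
        fc = select_elastic_net(Xc, y, seed=fit_seed)
        fa = select_elastic_net(Xa, y, seed=fit_seed)
        aic_c, bic_c = aic_bic(fc, Xc, y)
        aic_a, bic_a = aic_bic(fa, Xa, y)
        aic_pref += aic_a < aic_c
        bic_pref += bic_a < bic_c
    return {"aic": aic_pref / n_sims, "bic": bic_pref / n_sims,
            "n_sims": n_sims}


def true_effect_size(spec: CohortSpec, n_sessions: int = 4000,
                     seed: int = 12345, metric: str = "pb_misclass") -> float:
    """Planted standardised effect: the population-level Cohen's d of the
    session-2-minus-baseline bias change between the two response classes,
    estimated from a large independent simulation."""
    rng = np.random.default_rng(seed)
    base = ResponseModel.default()
    j = METRICS.index(metric)

    def _deltas(delta: float) -> np.ndarray:
        m = base.with_positivity_shift(delta)
        return (batch_bias_scores(m, n_sessions, rng)[:, j]
                - batch_bias_scores(base, n_sessions, rng)[:, j])

    d_r = _deltas(spec.delta_responder)
    d_n = _deltas(spec.delta_nonresponder)
    sp = np.sqrt((d_r.var(ddof=1) + d_n.var(ddof=1)) / 2.0)
    return float((d_r.mean() - d_n.mean()) / sp)
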