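"""Scoring of the facial expression recognition task (FERT).

Four positive-bias metrics are computed per session, each a log-transformed
ratio of a performance metric for positive ({happy, surprise}) versus
negative ({fear, sadness, anger, disgust}) emotions, signed so that a higher
value always means a more positive bias:

* ``pb_ubh``        — ln(mean unbiased hit rate, positive / negative).
* ``pb_rt``         — ln(mean median correct RT, negative / positive);
                      faster responding to positive faces is a positive bias.
* ``pb_efficiency`` — ln(mean efficiency, positive / negative), where
                      efficiency = unbiased hit rate / median correct RT.
* ``pb_misclass``   — ln(misclassifications *as* positive / *as* negative):
                      a response-criterion measure, counted over erroneous
                      choices of a positive vs negative label regardless of
                      the true emotion (responses of "neutral" are excluded;
                      errors on neutral-face trials count when an emotional
                      label was chosen).

The unbiased hit rate (signal-detection theory) multiplies the hit fraction
for an emotion by the precision with which its label was used:
hit_fraction * (times correctly chosen / times chosen at all).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import (
    EMOTIONS,
    EMOTION_INDEX,
    NEGATIVE_EMOTIONS,
    POSITIVE_EMOTIONS,
)

METRICS = ("pb_ubh", "pb_rt", "pb_efficiency", "pb_misclass")


class UndefinedMetricError(ValueError):
    """A metric's preconditions are not met (e.g. emotion never presented)."""


def _session_arrays(trials: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integer-coded (true, response, rt) arrays; response -1 = missing."""
    if len(trials) == 0:
        raise ValueError("empty trial table")
    ti = pd.Categorical(trials.true_emotion, categories=EMOTIONS).codes
    if (ti < 0).any():
        bad = sorted(set(trials.true_emotion) - set(EMOTIONS))
        raise ValueError(f"unknown emotion labels: {bad}")
    ri = pd.Categorical(trials.response_emotion, categories=EMOTIONS).codes
    if ((ri < 0) & trials.response_emotion.notna().to_numpy()).any():
        bad = sorted(set(trials.response_emotion.dropna()) - set(EMOTIONS))
        raise ValueError(f"unknown response labels: {bad}")
    return ti.astype(np.intp), ri.astype(np.intp), trials.rt_ms.to_numpy(dtype=float)


def _confusion_counts(ti: np.ndarray, ri: np.ndarray) -> np.ndarray:
    valid = ri >= 0
    return np.bincount(ti[valid] * 7 + ri[valid], minlength=49).reshape(7, 7)


def confusion_matrix(trials: pd.DataFrame) -> pd.DataFrame:
    """7x7 confusion matrix of counts, rows = true emotion, columns = chosen.

    Trials with a missing response are excluded (the count of exclusions is
    attached as ``conf.attrs["n_missing"]``).
    """
    ti, ri, _ = _session_arrays(trials)
    counts = _confusion_counts(ti, ri)
    conf = pd.DataFrame(counts, index=list(EMOTIONS), columns=list(EMOTIONS))
    conf.attrs["n_missing"] = int((ri < 0).sum())
    return conf


def hit_fraction(conf: pd.DataFrame, emotion: str) -> float:
    presented = conf.loc[emotion].sum()
    if presented == 0:
        raise UndefinedMetricError(f"{emotion} never presented")
    return conf.loc[emotion, emotion] / presented


def unbiased_hit_rate(conf: pd.DataFrame, emotion: str) -> float:
    """Hit fraction times label precision; 0 when the label was never used
    (the hit numerator is then necessarily 0)."""
    hf = hit_fraction(conf, emotion)
    chosen_total = conf[emotion].sum()
    if chosen_total == 0:
        return 0.0
    return float(hf * conf.loc[emotion, emotion] / chosen_total)


def misclassification_count(conf: pd.DataFrame, emotion: str) -> int:
    """Number of times `emotion` was chosen when it was not the true one."""
    return int(conf[emotion].sum() - conf.loc[emotion, emotion])


def median_rt_correct(trials: pd.DataFrame, emotion: str) -> float:
    """Median RT over correctly identified trials of `emotion` (midpoint
    convention for even counts)."""
    rts = trials.loc[(trials.true_emotion == emotion) & trials.correct, "rt_ms"]
    if len(rts) == 0:
        raise UndefinedMetricError(f"no correct trials for {emotion}")
    return float(np.median(rts))


def _metric_arrays(ti: np.ndarray, ri: np.ndarray, rt: np.ndarray) -> dict[str, np.ndarray]:
    """All per-emotion metrics as length-7 arrays (numpy core)."""
    counts = _confusion_counts(ti, ri)
    diag = np.diag(counts).astype(float)
    presented = counts.sum(axis=1).astype(float)
    chosen = counts.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        hf = np.where(presented > 0, diag / presented, np.nan)
        precision = np.where(chosen > 0, diag / chosen, 0.0)
    ubh = np.where(presented > 0, hf * precision, np.nan)
    med = np.full(7, np.nan)
    correct = ti == ri
    for e in range(7):
        sel = rt[correct & (ti == e)]
        if sel.size:
            med[e] = np.median(sel)
    with np.errstate(invalid="ignore"):
        eff = ubh / med
    return {
        "hit_fraction": hf, "chosen_correct": diag, "chosen_total": chosen,
        "ubh": ubh, "median_rt_ms": med, "efficiency": eff,
        "misclassification_count": chosen - diag,
        "n_missing": int((ri < 0).sum()),
    }


def emotion_metrics(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-emotion performance table: hit fraction, unbiased hit rate,
    median correct RT, efficiency and misclassification count."""
    ti, ri, rt = _session_arrays(trials)
    m = _metric_arrays(ti, ri, rt)
    out = pd.DataFrame({
        "hit_fraction": m["hit_fraction"],
        "chosen_correct": m["chosen_correct"].astype(int),
        "chosen_total": m["chosen_total"].astype(int),
        "ubh": m["ubh"],
        "median_rt_ms": m["median_rt_ms"],
        "efficiency": m["efficiency"],
        "misclassification_count": m["misclassification_count"].astype(int),
    }, index=pd.Index(list(EMOTIONS), name="emotion"))
    out.attrs["n_missing"] = m["n_missing"]
    return out


@dataclass
class BiasScores:
    """The four log-ratio positive-bias scores for one session.

    ``valid`` flags metrics whose preconditions held; ``flags`` records
    boundary handling (zero-cell continuity correction, never-chosen
    labels, missing responses).
    """

    pb_ubh: float
    pb_rt: float
    pb_efficiency: float
    pb_misclass: float
    valid: dict[str, bool] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def as_series(self) -> pd.Series:
        return pd.Series({m: getattr(self, m) for m in METRICS})


def positive_bias_scores(
    trials: pd.DataFrame,
    positive: tuple[str, ...] = POSITIVE_EMOTIONS,
    negative: tuple[str, ...] = NEGATIVE_EMOTIONS,
) -> BiasScores:
    """Compute the four positive-bias scores from one session's trials.

    Per-emotion metrics are averaged (arithmetic mean) within each valence
    before taking the ratio; misclassification counts are pooled across
    response categories since they are event counts.  If either pooled
    misclassification sum is 0, 0.5 is added to both (Haldane-style
    continuity correction) and the score is flagged.  Exchanging the
    ``positive`` and ``negative`` sets negates every defined score exactly.
    """
    ti, ri, rt = _session_arrays(trials)
    m = _metric_arrays(ti, ri, rt)
    flags: list[str] = []
    valid: dict[str, bool] = {}
    if m["n_missing"]:
        flags.append(f"missing_responses:{m['n_missing']}")

    pos_idx = [EMOTION_INDEX[e] for e in positive]
    neg_idx = [EMOTION_INDEX[e] for e in negative]

    def _log_ratio(num: float, den: float, metric: str) -> float:
        if not np.isfinite(num) or not np.isfinite(den) or num <= 0 or den <= 0:
            valid[metric] = False
            flags.append(f"{metric}:zero_or_undefined")
            return np.nan
        valid[metric] = True
        # difference of logs, so exchanging the valence sets negates the
        # score exactly (bitwise), not just to rounding
        return float(np.log(num) - np.log(den))

    if (m["chosen_total"][pos_idx + neg_idx] == 0).any():
        flags.append("label_never_chosen")

    pb_ubh = _log_ratio(m["ubh"][pos_idx].mean(), m["ubh"][neg_idx].mean(), "pb_ubh")
    pb_rt = _log_ratio(m["median_rt_ms"][neg_idx].mean(),
                       m["median_rt_ms"][pos_idx].mean(), "pb_rt")
    pb_eff = _log_ratio(m["efficiency"][pos_idx].mean(),
                        m["efficiency"][neg_idx].mean(), "pb_efficiency")

    mis_pos = float(m["misclassification_count"][pos_idx].sum())
    mis_neg = float(m["misclassification_count"][neg_idx].sum())
    if mis_pos == 0 or mis_neg == 0:
        mis_pos += 0.5
        mis_neg += 0.5
        flags.append("pb_misclass:continuity_corrected")
    valid["pb_misclass"] = True
    pb_mis = float(np.log(mis_pos) - np.log(mis_neg))

    return BiasScores(pb_ubh=pb_ubh, pb_rt=pb_rt, pb_efficiency=pb_eff,
                      pb_misclass=pb_mis, valid=valid, flags=flags)


def bias_change(baseline: BiasScores, week2: BiasScores) -> pd.Series:
    """Per-metric change (week 2 minus baseline); positive = increase in
    positive bias.  A metric invalid in either session yields NaN."""
    out = {}
    for m in METRICS:
        ok = baseline.valid.get(m, True) and week2.valid.get(m, True)
        b, w = getattr(baseline, m), getattr(week2, m)
        out[m] = (w - b) if ok and np.isfinite(b) and np.isfinite(w) else np.nan
    return pd.Series(out)
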