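"""Clinical outcome derivation from weekly HAM-D series.

The primary endpoint is HAM-D improvement from baseline to the end of
treatment (week 4): improvement = s(0) - s(4), positive = symptom
reduction.  *Clinical response* is a >= 50% reduction of the baseline score
at week 4.  A missing week-4 score can be imputed by fitting an exponential
decay to the observed reduction scores r(t) = s(0) - s(t) over weeks 0-3:
r(t) = A (1 - e^{-k t}), and predicting r(4).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


class MissingEndpointError(ValueError):
    """Week-4 score unavailable and imputation disabled or impossible."""


@dataclass
class ImputationReport:
    """Least-squares fit report for the exponential-decay imputation."""

    A: float
    k: float
    rss: float
    imputed_week4: float
    method: str  # "exponential_decay" or "locf"


@dataclass
class OutcomeLabels:
    participant_id: str | None
    hamd_baseline: float
    hamd_week4: float
    hamd_improvement: float
    responder: bool
    percent_change: pd.Series  # index = week, 100*(s(t)-s(0))/s(0)
    imputation: ImputationReport | None = None


def _series_dict(series: pd.DataFrame) -> dict[int, float]:
    s = series.dropna(subset=["score"])
    return dict(zip(s.week.astype(int), s.score.astype(float)))


def _decay(t: np.ndarray, A: float, k: float) -> np.ndarray:
    return A * (1.0 - np.exp(-k * t))


def impute_week4(series: pd.DataFrame) -> ImputationReport:
    """Impute a missing week-4 score from weeks 0-3.

    Fits r(t) = A (1 - e^{-kt}) with A, k >= 0 to the observed reductions by
    multi-start least squares and predicts the week-4 reduction.  On fit
    failure, falls back to last observation carried forward (flagged in the
    report's ``method``).
    """
    obs = _series_dict(series)
    needed = [0, 1, 2, 3]
    if any(w not in obs for w in needed):
        raise MissingEndpointError("weeks 0-3 required for imputation")
    t = np.array(needed, dtype=float)
    r = obs[0] - np.array([obs[w] for w in needed])
    if np.allclose(r, 0.0):
        return ImputationReport(A=0.0, k=0.0, rss=0.0,
                                imputed_week4=obs[0], method="exponential_decay")
    best = None
    for k0 in (0.1, 0.5, 1.0, 2.0):
        try:
            popt, _ = curve_fit(
                _decay, t, r, p0=[max(r.max(), 1e-3), k0],
                bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10000,
            )
        except RuntimeError:
            continue
        rss = float(np.sum((_decay(t, *popt) - r) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        return ImputationReport(A=np.nan, k=np.nan, rss=np.nan,
                                imputed_week4=obs[3], method="locf")
    (A, k), rss = best
    r4 = _decay(np.array([4.0]), A, k)[0]
    return ImputationReport(A=float(A), k=float(k), rss=rss,
                            imputed_week4=float(obs[0] - r4),
                            method="exponential_decay")


def derive_outcomes(series: pd.DataFrame, impute: bool = True,
                    participant_id: str | None = None) -> OutcomeLabels:
    """Derive improvement, responder label and weekly percent change.

    A reduction of exactly 50% counts as response.  ``series`` is a long
    frame with ``week`` and ``score`` columns (optionally NaN scores).
    """
    obs = _series_dict(series)
    if 0 not in obs:
        raise MissingEndpointError("week 0 (baseline) score required")
    s0 = obs[0]
    report = None
    if 4 in obs:
        s4 = obs[4]
    elif impute:
        report = impute_week4(series)
        s4 = report.imputed_week4
    else:
        raise MissingEndpointError("week 4 missing and imputation disabled")
    improvement = s0 - s4
    responder = s0 > 0 and improvement / s0 >= 0.5
    pct = pd.Series(
        {w: 100.0 * (obs[w] - s0) / s0 for w in sorted(obs)}, name="percent_change"
    )
    return OutcomeLabels(
        participant_id=participant_id, hamd_baseline=s0, hamd_week4=s4,
        hamd_improvement=improvement, responder=bool(responder),
        percent_change=pct, imputation=report,
    )


def outcomes_table(hamd_long: pd.DataFrame, impute: bool = True) -> pd.DataFrame:
    """Derive outcomes for every participant in a long HAM-D frame
    (columns participant_id, week, score)."""
    rows = []
    for pid, grp in hamd_long.groupby("participant_id", sort=True):
        lab = derive_outcomes(grp, impute=impute, participant_id=pid)
        rows.append({
            "participant_id": pid,
            "hamd_baseline": lab.hamd_baseline,
            "hamd_week4": lab.hamd_week4,
            "hamd_improvement": lab.hamd_improvement,
            "responder": lab.responder,
            "imputed": lab.imputation is not None,
        })
    return pd.DataFrame(rows)
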