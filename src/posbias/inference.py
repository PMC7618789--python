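"""Group-level behavioural statistics.

Implements the statistical battery applied to the FERT bias scores and
clinical outcomes: mixed (split-plot) ANOVAs with Time as within-subject
and Clinical Response as between-subject factor, covariate-adjusted
logistic and linear regressions, Bonferroni correction over the four bias
metrics, Cohen's d with a noncentral-t confidence interval, and
baseline-characteristics tests (Welch t / Fisher exact).

The split-plot ANOVA is computed from orthonormal within-subject contrasts:
each within stratum (e.g. Time, Emotion, Emotion x Time) is projected out
per subject and analysed as a one-way ANOVA over the between-subject
groups, which yields the classical sphericity-assumed univariate F tests
(sequential sums of squares, matching R's ``aov`` with an
``Error(subject/(A*B))`` term).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .design import NON_NEUTRAL
from .fert import METRICS, bias_change, emotion_metrics, positive_bias_scores
from .outcomes import outcomes_table

COVARIATES = ("hamd_baseline", "age", "gender_female", "medication", "n_itbs_sessions")


class InsufficientDataError(ValueError):
    """A response class has too few participants for the requested test."""


@dataclass
class TestResult:
    """One statistical test: statistic, df, p, effect size and metadata."""

    name: str
    statistic: float
    stat_name: str
    df: tuple[float, ...] | float
    p: float
    p_corrected: float | None = None
    effect: float | None = None
    effect_name: str | None = None
    effect_ci: tuple[float, float] | None = None
    n: int | None = None
    extras: dict = field(default_factory=dict)


# --- analysis frame assembly ----------------------------------------------


def analysis_frame_from_cohort(cohort, response_from: str = "observed") -> pd.DataFrame:
    """Build the participant-level analysis frame from a cohort dataset.

    One row per participant: the four bias scores at each session and their
    deltas, the responder label (``observed`` = derived from the HAM-D
    series, ``true`` = the generator's class tag), HAM-D improvement and the
    five control covariates.
    """
    out = outcomes_table(cohort.hamd)
    rows = []
    for _, part in cohort.participants.iterrows():
        pid = part.participant_id
        base = positive_bias_scores(cohort.fert[(pid, "baseline")])
        wk2 = positive_bias_scores(cohort.fert[(pid, "week2")])
        delta = bias_change(base, wk2)
        row = {"participant_id": pid}
        for m in METRICS:
            row[f"{m}_baseline"] = getattr(base, m)
            row[f"{m}_week2"] = getattr(wk2, m)
            row[f"{m}_delta"] = delta[m]
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame = frame.merge(cohort.participants, on="participant_id")
    frame = frame.merge(out, on="participant_id")
    frame["gender_female"] = (frame.gender == "F").astype(float)
    frame["medication"] = frame.medication.astype(float)
    if response_from == "true":
        frame["response"] = np.where(frame.true_class == "responder",
                                     "responder", "non-responder")
    else:
        frame["response"] = np.where(frame.responder, "responder", "non-responder")
    return frame


def per_emotion_session_values(cohort, metric: str = "misclass") -> pd.DataFrame:
    """Long per-emotion values for the emotion-resolved follow-up ANOVA.

    For each participant, session and non-neutral emotion, the per-emotion
    component of the requested metric: unbiased hit rate (``ubh``), median
    correct RT (``rt``), efficiency, or log(misclassification count + 0.5)
    (``misclass``).
    """
    rows = []
    for (pid, session), trials in cohort.fert.items():
        em = emotion_metrics(trials)
        for emo in NON_NEUTRAL:
            if metric == "ubh":
                val = em.loc[emo, "ubh"]
            elif metric == "rt":
                val = em.loc[emo, "median_rt_ms"]
            elif metric == "efficiency":
                val = em.loc[emo, "efficiency"]
            elif metric == "misclass":
                val = np.log(em.loc[emo, "misclassification_count"] + 0.5)
            else:
                raise ValueError(f"unknown metric {metric!r}")
            rows.append({"participant_id": pid, "session": session,
                         "emotion": emo, "value": val})
    return pd.DataFrame(rows)


# --- split-plot ANOVA engine ----------------------------------------------


def _helmert(k: int) -> np.ndarray:
    """k x (k-1) orthonormal contrast matrix (columns orthogonal to 1)."""
    h = np.zeros((k, k - 1))
    for j in range(1, k):
        h[:j, j - 1] = 1.0
        h[j, j - 1] = -j
        h[:, j - 1] /= np.sqrt(j * (j + 1))
    return h


def _f_ratio(ms_effect: float, ms_error: float) -> float:
    """Degenerate-input convention: a zero effect mean-square is F = 0 even
    when the error mean-square is also zero (e.g. all-zero change scores)."""
    if ms_error > 0:
        return ms_effect / ms_error
    return 0.0 if np.isclose(ms_effect, 0.0) else np.inf


def _within_stratum(Z: np.ndarray, groups: np.ndarray, labels: Sequence) -> tuple[float, float, float]:
    """Sequential SS for (effect, effect x group, error) in one within
    stratum given its orthonormal contrast scores Z (n x q)."""
    n = Z.shape[0]
    ss_eff = float((Z.sum(axis=0) ** 2).sum() / n)
    ss_cells = 0.0
    ss_err = 0.0
    for g in labels:
        zg = Z[groups == g]
        ss_cells += float((zg.sum(axis=0) ** 2).sum() / len(zg))
        ss_err += float(((zg - zg.mean(axis=0)) ** 2).sum())
    return ss_eff, ss_cells - ss_eff, ss_err


def split_plot_anova(
    y: np.ndarray,
    groups: np.ndarray,
    within_names: tuple[str, ...] = ("time",),
    between_name: str = "response",
) -> pd.DataFrame:
    """Univariate mixed ANOVA with one between factor and one or two fully
    crossed within factors.

    ``y`` has shape (n_subjects, a, b) for within factors of a and b levels
    (a = 1 collapses to a single within factor).  Returns a tidy table of
    F tests per effect, sphericity assumed.
    """
    if y.ndim == 2:
        y = y[:, None, :]
    n, a, b = y.shape
    labels = pd.unique(groups)
    counts = pd.Series(groups).value_counts()
    if len(labels) < 2 or (counts < 2).any():
        raise InsufficientDataError("need >= 2 participants per response class")
    g = len(labels)
    ymat = y.reshape(n, a * b)
    # sums of squares this far below the data's magnitude are rounding
    # residue of exact cancellations; snap them to zero so degenerate
    # inputs (e.g. all-zero change scores) give F = 0 rather than 0/0
    ss_tol = float((ymat**2).sum()) * 1e-24

    def _snap(ss: float) -> float:
        return 0.0 if ss < ss_tol else ss

    rows = []
    # between stratum: subject means
    z0 = ymat.mean(axis=1)
    gm = z0.mean()
    ss_b = _snap(sum(counts[l] * (z0[groups == l].mean() - gm) ** 2 for l in labels))
    ss_be = _snap(sum(((z0[groups == l] - z0[groups == l].mean()) ** 2).sum()
                      for l in labels))
    ms_be = ss_be / (n - g)
    rows.append((between_name, ss_b, g - 1, ss_be, n - g,
                 _f_ratio(ss_b / (g - 1), ms_be)))

    ha = _helmert(a) if a > 1 else None
    hb = _helmert(b) if b > 1 else None
    one_a = np.full((a, 1), 1 / np.sqrt(a))
    one_b = np.full((b, 1), 1 / np.sqrt(b))

    strata = []
    if a > 1:
        strata.append((within_names[0], np.kron(ha, one_b), a - 1))
    if b > 1:
        tname = within_names[-1]
        strata.append((tname, np.kron(one_a, hb), b - 1))
    if a > 1 and b > 1:
        strata.append((f"{within_names[0]}*{within_names[-1]}",
                       np.kron(ha, hb), (a - 1) * (b - 1)))

    for name, C, q in strata:
        Z = ymat @ C
        ss_eff, ss_int, ss_err = _within_stratum(Z, groups, labels)
        ss_eff, ss_int, ss_err = _snap(ss_eff), _snap(ss_int), _snap(ss_err)
        df_err = q * (n - g)
        ms_err = ss_err / df_err
        rows.append((name, ss_eff, q, ss_err, df_err,
                     _f_ratio(ss_eff / q, ms_err)))
        rows.append((f"{name}*{between_name}", ss_int, q * (g - 1), ss_err, df_err,
                     _f_ratio(ss_int / (q * (g - 1)), ms_err)))

    table = pd.DataFrame(rows, columns=["effect", "ss", "df1", "ss_error", "df2", "F"])
    table["p"] = stats.f.sf(table.F, table.df1, table.df2)
    return table


def mixed_anova_time_by_response(frame: pd.DataFrame, metric: str) -> TestResult:
    """Time (baseline vs week 2, within) x Clinical Response (between)
    mixed ANOVA on one bias metric; the headline test is the interaction."""
    cols = [f"{metric}_baseline", f"{metric}_week2"]
    sub = frame.dropna(subset=cols + ["response"])
    y = sub[cols].to_numpy()[:, None, :]
    table = split_plot_anova(y, sub.response.to_numpy(), within_names=("time",))
    inter = table[table.effect == "time*response"].iloc[0]
    return TestResult(
        name=f"{metric}: time x response interaction",
        statistic=float(inter.F), stat_name="F",
        df=(float(inter.df1), float(inter.df2)), p=float(inter.p),
        n=len(sub), extras={"anova_table": table},
    )


def emotion_followup_anova(values: pd.DataFrame, frame: pd.DataFrame) -> TestResult:
    """Emotion (6) x Time (2) within, Clinical Response between, on the
    per-emotion metric values; the headline test is the three-way
    interaction (is the Time x Response effect emotion-specific?)."""
    wide = values.pivot_table(index="participant_id", columns=["emotion", "session"],
                              values="value")
    wide = wide.reindex(
        columns=pd.MultiIndex.from_product([NON_NEUTRAL, ("baseline", "week2")]))
    resp = frame.set_index("participant_id").response
    wide = wide.dropna()
    groups = resp.loc[wide.index].to_numpy()
    y = wide.to_numpy().reshape(len(wide), len(NON_NEUTRAL), 2)
    table = split_plot_anova(y, groups, within_names=("emotion", "time"))
    inter = table[table.effect == "emotion*time*response"].iloc[0]
    return TestResult(
        name="emotion x time x response interaction",
        statistic=float(inter.F), stat_name="F",
        df=(float(inter.df1), float(inter.df2)), p=float(inter.p),
        n=len(wide), extras={"anova_table": table},
    )


# --- regressions -----------------------------------------------------------


def _design_matrix(frame: pd.DataFrame, predictor: str,
                   covariates: Sequence[str] = COVARIATES) -> pd.DataFrame:
    cols = [predictor, *covariates]
    X = frame[cols].astype(float).copy()
    X.insert(0, "intercept", 1.0)
    return X


def _check_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy()
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        _, r = np.linalg.qr(mat)
        bad = [X.columns[j] for j in range(mat.shape[1])
               if abs(r[j, j]) < 1e-8 * abs(r[0, 0])]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def _ml_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 100,
                 tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray, bool]:
    """Newton-Raphson maximum-likelihood logistic fit.

    Returns (beta, covariance, converged); diverging coefficients (as under
    separation) leave ``converged`` False.
    """
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        info = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(info, X.T @ (y - mu))
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    cov = np.linalg.pinv(X.T @ (X * w[:, None]))
    if np.max(np.abs(beta)) > 15:
        converged = False
    return beta, cov, converged


def _firth_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 100,
                    tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Firth bias-reduced logistic regression (Jeffreys-prior penalty).

    Returns (beta, covariance).  Used as fallback when the ordinary ML fit
    separates; the penalty keeps estimates finite.
    """
    n, p = X.shape
    beta = np.zeros(p)

    def _penalised_ll(b: np.ndarray) -> float:
        eta = np.clip(X @ b, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
        sign, logdet = np.linalg.slogdet(X.T @ (X * w[:, None]))
        return ll + 0.5 * (logdet if sign > 0 else -np.inf)

    ll_old = _penalised_ll(beta)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        info = X.T @ (X * w[:, None])
        info_inv = np.linalg.pinv(info)
        xw = X * np.sqrt(w)[:, None]
        h = np.einsum("ij,jk,ik->i", xw, info_inv, xw)
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ score
        # step-halving keeps the penalised likelihood ascent stable when
        # the information matrix is near singular (p close to n)
        for _ in range(12):
            ll_new = _penalised_ll(beta + step)
            if ll_new >= ll_old - 1e-12:
                break
            step = step / 2.0
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
        ll_old = ll_new
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    cov = np.linalg.pinv(X.T @ (X * w[:, None]))
    return beta, cov


def logistic_predict_response(frame: pd.DataFrame, metric: str,
                              covariates: Sequence[str] = COVARIATES) -> TestResult:
    """Logistic regression of Clinical Response on a bias-change regressor,
    adjusted for the five control covariates.

    Reports the Wald z and p for the bias coefficient, the odds ratio
    exp(beta) with 95% CI, and additionally the per-SD odds ratio
    exp(beta * sd(x)) since the regressor is on a log-ratio scale.
    On (quasi-)separation the fit falls back to Firth's penalised
    likelihood, flagged in ``extras``.
    """
    predictor = f"{metric}_delta"
    sub = frame.dropna(subset=[predictor, *covariates, "response"])
    dropped = [c for c in covariates if sub[c].nunique() <= 1]
    covariates = [c for c in covariates if c not in dropped]
    X = _design_matrix(sub, predictor, covariates)
    _check_rank(X)
    y = (sub.response == "responder").astype(float).to_numpy()
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise InsufficientDataError("need >= 2 participants per response class")
    method = "ml"
    beta, cov, converged = _ml_logistic(X.to_numpy(), y)
    if not converged:
        beta, cov = _firth_logistic(X.to_numpy(), y)
        method = "firth"
    se = np.sqrt(np.diag(cov))
    j = list(X.columns).index(predictor)
    z = beta[j] / se[j] if se[j] > 0 else np.nan
    p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
    ci = (np.exp(beta[j] - 1.96 * se[j]), np.exp(beta[j] + 1.96 * se[j]))
    sd_x = float(sub[predictor].std(ddof=1))
    return TestResult(
        name=f"{metric}: logistic regression on clinical response",
        statistic=float(z), stat_name="z", df=float(len(sub) - X.shape[1]),
        p=float(p), effect=float(np.exp(beta[j])), effect_name="odds_ratio",
        effect_ci=(float(ci[0]), float(ci[1])), n=len(sub),
        extras={"beta": float(beta[j]), "se": float(se[j]), "method": method,
                "odds_ratio_per_sd": float(np.exp(beta[j] * sd_x)),
                "dropped_constant_covariates": dropped},
    )


def linear_predict_improvement(frame: pd.DataFrame, predictor: str,
                               covariates: Sequence[str] = COVARIATES) -> TestResult:
    """OLS of HAM-D improvement on a predictor plus the control covariates;
    reports t, p and the raw coefficient for the predictor."""
    import statsmodels.api as sm

    sub = frame.dropna(subset=[predictor, *covariates, "hamd_improvement"])
    X = _design_matrix(sub, predictor, covariates)
    _check_rank(X)
    fit = sm.OLS(sub.hamd_improvement.astype(float).to_numpy(), X.to_numpy()).fit()
    j = list(X.columns).index(predictor)
    return TestResult(
        name=f"improvement ~ {predictor} + covariates",
        statistic=float(fit.tvalues[j]), stat_name="t",
        df=float(fit.df_resid), p=float(fit.pvalues[j]),
        effect=float(fit.params[j]), effect_name="beta", n=len(sub),
        extras={"r_squared": float(fit.rsquared)},
    )


# --- simple utilities ------------------------------------------------------


def bonferroni(p_values, m: int = 4) -> np.ndarray:
    """Bonferroni correction over the four bias metrics: min(1, m*p)."""
    p = np.asarray(p_values, dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, m * p)


def cohens_d(x, y, ci_level: float = 0.95) -> TestResult:
    """Pooled-SD standardised mean difference (x minus y) with a
    noncentral-t confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("need >= 2 observations per class")
    sp2 = (((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2))
    if sp2 <= 0:
        raise ValueError("zero pooled SD: d undefined")
    d = (x.mean() - y.mean()) / np.sqrt(sp2)
    df = n1 + n2 - 2
    scale = np.sqrt(1.0 / n1 + 1.0 / n2)
    t_obs = d / scale
    alpha = 1.0 - ci_level

    def _ncp_for(prob: float) -> float:
        def f(nc: float) -> float:
            v = stats.nct.cdf(t_obs, df, nc)
            if np.isnan(v):  # extreme-tail underflow: cdf is decreasing in nc
                v = 0.0 if nc > t_obs else 1.0
            return v - prob

        lo, hi = t_obs - 20 - 20 * abs(t_obs), t_obs + 20 + 20 * abs(t_obs)
        return brentq(f, lo, hi)

    ci = (_ncp_for(1 - alpha / 2) * scale, _ncp_for(alpha / 2) * scale)
    p = 2 * stats.t.sf(abs(t_obs), df)
    return TestResult(
        name="cohens_d", statistic=float(t_obs), stat_name="t", df=float(df),
        p=float(p), effect=float(d), effect_name="cohens_d",
        effect_ci=(float(ci[0]), float(ci[1])), n=n1 + n2,
        extras={"ci_method": "noncentral_t"},
    )


def baseline_table(frame: pd.DataFrame,
                   continuous: Sequence[str] = ("age", "hamd_baseline"),
                   categorical: Sequence[str] = ("gender_female", "medication"),
                   group_col: str = "response") -> pd.DataFrame:
    """Baseline-characteristics comparison between response classes:
    Welch two-sample t-tests for continuous variables, Fisher exact tests
    for binary ones."""
    g1 = frame[frame[group_col] == "responder"]
    g2 = frame[frame[group_col] == "non-responder"]
    rows = []
    for col in continuous:
        t, p = stats.ttest_ind(g1[col].dropna(), g2[col].dropna(), equal_var=False)
        rows.append({"variable": col, "test": "welch_t", "statistic": t, "p": p})
    for col in categorical:
        tab = np.array([
            [(g1[col] == 1).sum(), (g1[col] != 1).sum()],
            [(g2[col] == 1).sum(), (g2[col] != 1).sum()],
        ])
        _, p = stats.fisher_exact(tab)
        rows.append({"variable": col, "test": "fisher_exact",
                     "statistic": np.nan, "p": p})
    return pd.DataFrame(rows)
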