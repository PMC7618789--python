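"""Elastic-net model comparison: does early bias change predict outcome
beyond early symptom change?

Two penalised linear models of end-of-treatment HAM-D improvement are
compared: a *clinical* model (early HAM-D change, baseline HAM-D, age,
gender, medication) and an *augmented* model adding the bias-change
features.  Out-of-sample performance is estimated by nested
cross-validation (inner folds select the elastic-net penalty and mixing
parameter, outer folds score R^2); in-sample fit is compared by AIC/BIC
with the degrees of freedom adjusted for regularisation:

    df = trace[ X_A (X_A' X_A + n * alpha * (1 - l1_ratio) I)^{-1} X_A' ]

restricted to the active (nonzero-coefficient) predictor set A, which
reduces to |A| in the pure-lasso limit and to the number of predictors at
zero penalty.  Gaussian forms are used with constants omitted:
AIC = n ln(RSS/n) + 2 df,  BIC = n ln(RSS/n) + df ln n.

Features are standardised with training-data statistics only; both models
are always scored on identical outer folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler

DEFAULT_L1_RATIOS = (0.1, 0.5, 0.9)
DEFAULT_N_ALPHAS = 20


@dataclass
class PenalisedFit:
    """A fitted elastic net (on standardised features) with its penalty."""

    coef: np.ndarray
    intercept: float
    alpha: float
    l1_ratio: float
    feature_names: list[str]
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    rss: float
    n: int

    @property
    def active_set(self) -> np.ndarray:
        return np.flatnonzero(self.coef != 0.0)


def _standardise(X: np.ndarray) -> tuple[np.ndarray, StandardScaler]:
    scaler = StandardScaler().fit(X)
    return scaler.transform(X), scaler


def fit_elastic_net(X: pd.DataFrame, y: np.ndarray, alpha: float,
                    l1_ratio: float) -> PenalisedFit:
    """Fit one elastic net at a fixed penalty (features standardised
    internally); alpha = 0 reproduces ordinary least squares."""
    Xa = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xs, scaler = _standardise(Xa)
    if alpha == 0.0:
        coef, *_ = np.linalg.lstsq(
            np.column_stack([Xs, np.ones(len(y))]), y, rcond=None)
        intercept = float(coef[-1])
        coef = coef[:-1]
    else:
        est = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, max_iter=50000)
        est.fit(Xs, y)
        coef, intercept = est.coef_, float(est.intercept_)
    pred = Xs @ coef + intercept
    return PenalisedFit(
        coef=np.asarray(coef), intercept=intercept, alpha=float(alpha),
        l1_ratio=float(l1_ratio),
        feature_names=list(X.columns) if hasattr(X, "columns") else
        [f"x{j}" for j in range(Xa.shape[1])],
        scaler_mean=scaler.mean_, scaler_scale=scaler.scale_,
        rss=float(np.sum((y - pred) ** 2)), n=len(y),
    )


def effective_df(fit: PenalisedFit, X: pd.DataFrame) -> float:
    """Regularisation-adjusted degrees of freedom of an elastic-net fit.

    Trace of the ridge-type hat operator of the fit's ridge component on
    the active set (singular systems are handled by pseudo-inverse).
    """
    A = fit.active_set
    if fit.alpha == 0.0:
        return float(np.asarray(X).shape[1])
    if len(A) == 0:
        return 0.0
    Xs = (np.asarray(X, dtype=float) - fit.scaler_mean) / fit.scaler_scale
    Xa = Xs[:, A]
    lam2 = fit.n * fit.alpha * (1.0 - fit.l1_ratio)
    G = Xa.T @ Xa + lam2 * np.eye(len(A))
    return float(np.trace(Xa @ np.linalg.pinv(G) @ Xa.T))


def aic_bic(fit: PenalisedFit, X: pd.DataFrame, y: np.ndarray) -> tuple[float, float]:
    """Gaussian AIC/BIC with regularisation-adjusted df (constants omitted
    consistently across compared models)."""
    df = effective_df(fit, X)
    n = fit.n
    if fit.rss <= 0:
        return -np.inf, -np.inf
    base = n * np.log(fit.rss / n)
    return float(base + 2.0 * df), float(base + df * np.log(n))


def default_grid(X: pd.DataFrame, y: np.ndarray,
                 l1_ratios=DEFAULT_L1_RATIOS,
                 n_alphas: int = DEFAULT_N_ALPHAS) -> dict:
    return {"l1_ratio": list(l1_ratios), "n_alphas": n_alphas}


def select_elastic_net(X: pd.DataFrame, y: np.ndarray, k_inner: int = 5,
                       seed: int = 0, l1_ratios=DEFAULT_L1_RATIOS,
                       n_alphas: int = DEFAULT_N_ALPHAS) -> PenalisedFit:
    """Select (alpha, l1_ratio) by k-fold CV over the penalty grid and
    refit on all supplied rows (standardised internally)."""
    Xa = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xs, _ = _standardise(Xa)
    cv = KFold(n_splits=k_inner, shuffle=True, random_state=seed)
    est = ElasticNetCV(l1_ratio=list(l1_ratios), alphas=n_alphas, cv=cv,
                       max_iter=50000)
    est.fit(Xs, y)
    return fit_elastic_net(X, y, alpha=float(est.alpha_),
                           l1_ratio=float(est.l1_ratio_))


@dataclass
class CVReport:
    fold_r2: np.ndarray
    chosen: list[tuple[float, float]]  # (alpha, l1_ratio) per outer fold
    fold_assignment: np.ndarray

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.fold_r2))

    @property
    def sd_r2(self) -> float:
        return float(np.std(self.fold_r2, ddof=1))


def nested_cv_r2(X: pd.DataFrame, y: np.ndarray, k_outer: int = 5,
                 k_inner: int = 5, seed: int = 0,
                 l1_ratios=DEFAULT_L1_RATIOS,
                 n_alphas: int = DEFAULT_N_ALPHAS) -> CVReport:
    """Nested cross-validation: inner folds select the penalty per outer
    fold; outer folds score out-of-sample R^2.  Standardisation statistics
    come from the outer-training rows only; the fold assignment is fully
    determined by ``seed``.
    """
    Xa = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < k_outer or k_outer < 2:
        raise ValueError("need n >= k_outer >= 2")
    outer = KFold(n_splits=k_outer, shuffle=True, random_state=seed)
    fold_r2, chosen = [], []
    assignment = np.empty(n, dtype=int)
    for f, (tr, te) in enumerate(outer.split(Xa)):
        if len(te) < 2:
            raise ValueError("outer fold with < 2 observations")
        assignment[te] = f
        scaler = StandardScaler().fit(Xa[tr])
        Xtr, Xte = scaler.transform(Xa[tr]), scaler.transform(Xa[te])
        inner = KFold(n_splits=k_inner, shuffle=True, random_state=seed + 1)
        est = ElasticNetCV(l1_ratio=list(l1_ratios), alphas=n_alphas,
                           cv=inner, max_iter=50000)
        est.fit(Xtr, y[tr])
        fold_r2.append(r2_score(y[te], est.predict(Xte)))
        chosen.append((float(est.alpha_), float(est.l1_ratio_)))
    return CVReport(fold_r2=np.asarray(fold_r2), chosen=chosen,
                    fold_assignment=assignment)


@dataclass
class ComparisonReport:
    """Side-by-side evaluation of the clinical and augmented models."""

    cv_clinical: CVReport
    cv_augmented: CVReport
    aic: dict[str, float]
    bic: dict[str, float]
    effective_df: dict[str, float]
    delta_r2: float = field(init=False)
    preferred: dict[str, str] = field(init=False)

    def __post_init__(self) -> None:
        self.delta_r2 = self.cv_augmented.mean_r2 - self.cv_clinical.mean_r2
        self.preferred = {
            "aic": min(self.aic, key=self.aic.get),
            "bic": min(self.bic, key=self.bic.get),
            "cv_r2": ("augmented" if self.delta_r2 > 0
                      else "clinical" if self.delta_r2 < 0 else "tie"),
        }

    @property
    def folds_shared(self) -> bool:
        return bool(np.array_equal(self.cv_clinical.fold_assignment,
                                   self.cv_augmented.fold_assignment))

    def to_dict(self) -> dict:
        return {
            "r2": {"clinical": self.cv_clinical.mean_r2,
                   "augmented": self.cv_augmented.mean_r2,
                   "sd_clinical": self.cv_clinical.sd_r2,
                   "sd_augmented": self.cv_augmented.sd_r2,
                   "delta": self.delta_r2},
            "aic": self.aic, "bic": self.bic,
            "effective_df": self.effective_df,
            "preferred": self.preferred,
            "folds_shared": self.folds_shared,
        }


def compare_models(X_clinical: pd.DataFrame, X_augmented: pd.DataFrame,
                   y: np.ndarray, k_outer: int = 5, k_inner: int = 5,
                   seed: int = 0, l1_ratios=DEFAULT_L1_RATIOS,
                   n_alphas: int = DEFAULT_N_ALPHAS) -> ComparisonReport:
    """Evaluate both models on identical outer folds and compare by
    out-of-sample R^2 and by regularisation-adjusted AIC/BIC."""
    if len(X_clinical) != len(X_augmented) or len(X_clinical) != len(y):
        raise ValueError("mismatched sample rows across models")
    cv_c = nested_cv_r2(X_clinical, y, k_outer, k_inner, seed, l1_ratios, n_alphas)
    cv_a = nested_cv_r2(X_augmented, y, k_outer, k_inner, seed, l1_ratios, n_alphas)
    aic, bic, eff = {}, {}, {}
    for name, X in (("clinical", X_clinical), ("augmented", X_augmented)):
        fit = select_elastic_net(X, y, k_inner=k_inner, seed=seed,
                                 l1_ratios=l1_ratios, n_alphas=n_alphas)
        a, b = aic_bic(fit, X, y)
        aic[name], bic[name] = a, b
        eff[name] = effective_df(fit, X)
    return ComparisonReport(cv_clinical=cv_c, cv_augmented=cv_a,
                            aic=aic, bic=bic, effective_df=eff)
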