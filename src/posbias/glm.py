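"""Miniature voxelwise task-fMRI engine.

Reproduces the three-level structure of a block-design emotional-faces
analysis on desk-scale synthetic volumes:

* first level: per-run GLM with HRF-convolved happy/fearful regressors,
  their temporal derivatives, six motion regressors and an intercept
  (fixation is the implicit baseline), with contrasts Happy > Fearful,
  Happy > Fixation and Fearful > Fixation;
* second level: per-participant session change (week 2 minus baseline) of
  the contrast estimates;
* third level: group GLM of the change maps on HAM-D improvement with five
  de-meaned control covariates, with family-wise-error control by
  Freedman-Lane max-statistic permutation, whole brain or restricted to
  small ROI volumes at alpha = 0.05/6.

Psychophysiological interaction (PPI) designs add the seed timecourse and
its products with the (zero-centred) task regressors; the PPI contrast
(happy x seed) - (fearful x seed) asks where coupling with the seed is
stronger during happy than fearful blocks.

Estimation is ordinary least squares throughout (the synthetic data are
generated with white noise); no autocorrelation prewhitening is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .design import EventSchedule

ROI_ALPHA = 0.05 / 6

DEFAULT_HRF_LAG = 6.0
DEFAULT_HRF_DISPERSION = 3.0


def gamma_hrf(dt: float, lag: float = DEFAULT_HRF_LAG,
              dispersion: float = DEFAULT_HRF_DISPERSION,
              duration: float = 32.0) -> np.ndarray:
    """Discrete gamma hemodynamic response kernel.

    Parameterised by its mean ``lag`` (s) and standard deviation
    ``dispersion`` (s) — the convention of FSL-style gamma HRFs — sampled
    every ``dt`` seconds over ``duration`` and normalised to sum to 1, so
    that convolving a sustained unit boxcar plateaus at 1.
    """
    if dt <= 0 or lag <= 0 or dispersion <= 0:
        raise ValueError("dt, lag and dispersion must be positive")
    shape = (lag / dispersion) ** 2
    scale = dispersion**2 / lag
    t = np.arange(0.0, duration, dt)
    kernel = stats.gamma.pdf(t, a=shape, scale=scale)
    return kernel / kernel.sum()


def _stimulus_function(events: pd.DataFrame, dt: float, n_fine: int) -> np.ndarray:
    stim = np.zeros(n_fine)
    for onset, duration in zip(events.onset, events.duration):
        i0 = int(round(onset / dt))
        i1 = max(i0 + 1, int(round((onset + duration) / dt)))
        stim[i0:min(i1, n_fine)] = 1.0
    return stim


def task_regressors(schedule: EventSchedule, dt: float = 0.1,
                    hrf_lag: float = DEFAULT_HRF_LAG,
                    hrf_dispersion: float = DEFAULT_HRF_DISPERSION) -> tuple[np.ndarray, np.ndarray]:
    """HRF-convolved happy and fearful regressors sampled at the TR grid."""
    n_fine = int(np.ceil(schedule.n_volumes * schedule.tr / dt)) + 1
    kernel = gamma_hrf(dt, hrf_lag, hrf_dispersion)
    out = []
    for cond in ("happy", "fearful"):
        stim = _stimulus_function(schedule.face_events(cond), dt, n_fine)
        conv = np.convolve(stim, kernel)[:n_fine]
        idx = np.round(np.arange(schedule.n_volumes) * schedule.tr / dt).astype(int)
        out.append(conv[idx])
    return out[0], out[1]


def build_design(schedule: EventSchedule, motion: np.ndarray,
                 hrf_lag: float = DEFAULT_HRF_LAG,
                 hrf_dispersion: float = DEFAULT_HRF_DISPERSION) -> pd.DataFrame:
    """First-level design matrix: happy, fearful, their temporal
    derivatives (raw first differences), 6 motion regressors, intercept
    (11 columns; fixation is the implicit baseline)."""
    motion = np.asarray(motion, dtype=float)
    if motion.shape != (schedule.n_volumes, 6):
        raise ValueError(
            f"motion shape {motion.shape} != ({schedule.n_volumes}, 6)")
    xh, xf = task_regressors(schedule, hrf_lag=hrf_lag, hrf_dispersion=hrf_dispersion)
    cols = {
        "happy": xh,
        "fearful": xf,
        "happy_derivative": np.diff(xh, prepend=xh[0]),
        "fearful_derivative": np.diff(xf, prepend=xf[0]),
    }
    for j in range(6):
        cols[f"motion_{j + 1}"] = motion[:, j]
    cols["intercept"] = np.ones(schedule.n_volumes)
    return pd.DataFrame(cols)


@dataclass
class StatMap:
    """A named 3D statistic volume with its sign convention."""

    data: np.ndarray
    name: str
    kind: str  # "beta" | "t" | "p" | "p_fwe"
    sign: str = "bold_increase_positive"
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def as_negative_bold_change(self) -> "StatMap":
        """Flip sign so that an increase in *de-activation* (more negative
        BOLD) is reported as positive, tagged accordingly."""
        return replace(self, data=-self.data,
                       name=f"{self.name} (negative BOLD change)",
                       sign="deactivation_increase_positive")


def _ols_tmaps(Y: np.ndarray, X: np.ndarray, contrasts: dict[str, np.ndarray]
               ) -> tuple[np.ndarray, dict[str, tuple[np.ndarray, np.ndarray]]]:
    """OLS fit of Y (T x V) on X (T x p); per contrast returns (effect, t)."""
    T, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError("rank-deficient design matrix")
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    dof = T - rank
    sigma2 = (resid**2).sum(axis=0) / dof
    # residual variance this far below the data scale is rounding residue
    # of an exact fit; treat the voxel as degenerate (perfect fit)
    scale2 = (Y**2).mean(axis=0)
    sigma2 = np.where(sigma2 <= scale2 * 1e-20, 0.0, sigma2)
    xtx_inv = np.linalg.inv(X.T @ X)
    out = {}
    for name, c in contrasts.items():
        c = np.asarray(c, dtype=float)
        eff = c @ beta
        var = float(c @ xtx_inv @ c)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = eff / np.sqrt(var * sigma2)
        # perfect fits: zero residual variance gives t = 0 for a zero
        # effect (constant maps) and +/-inf for a nonzero one
        degenerate = sigma2 <= 0
        if degenerate.any():
            eff_zero = np.abs(eff) <= np.sqrt(scale2) * 1e-10
            signed_inf = np.where(eff > 0, np.inf, -np.inf)
            t = np.where(degenerate, np.where(eff_zero, 0.0, signed_inf), t)
            eff = np.where(degenerate & eff_zero, 0.0, eff)
        out[name] = (eff, t)
    return beta, out


FIRST_LEVEL_CONTRASTS = ("happy_gt_fearful", "happy_gt_fixation", "fearful_gt_fixation")


def _contrast_vector(columns: list[str], plus: str, minus: str | None = None) -> np.ndarray:
    c = np.zeros(len(columns))
    c[columns.index(plus)] = 1.0
    if minus is not None:
        c[columns.index(minus)] = -1.0
    return c


def fit_first_level(bold: np.ndarray, design: pd.DataFrame,
                    contrasts: tuple[str, ...] = FIRST_LEVEL_CONTRASTS
                    ) -> dict[str, dict[str, StatMap]]:
    """Voxelwise first-level GLM.

    ``bold`` is (x, y, z, t).  Returns, per contrast, ``beta`` (contrast of
    parameter estimates) and ``t`` maps.  Fixation carries no regressor, so
    "> fixation" contrasts are simply the task betas.
    """
    if bold.shape[-1] != len(design):
        raise ValueError("BOLD length does not match design rows")
    grid = bold.shape[:-1]
    Y = bold.reshape(-1, bold.shape[-1]).T
    cols = list(design.columns)
    cvecs = {
        "happy_gt_fearful": _contrast_vector(cols, "happy", "fearful"),
        "happy_gt_fixation": _contrast_vector(cols, "happy"),
        "fearful_gt_fixation": _contrast_vector(cols, "fearful"),
    }
    if "ppi_happy" in cols:
        cvecs["ppi_happy_gt_fearful"] = _contrast_vector(cols, "ppi_happy", "ppi_fearful")
    cvecs = {k: v for k, v in cvecs.items()
             if k in contrasts or k == "ppi_happy_gt_fearful"}
    _, fitted = _ols_tmaps(Y, design.to_numpy(), cvecs)
    out = {}
    for name, (eff, t) in fitted.items():
        out[name] = {
            "beta": StatMap(eff.reshape(grid), name=name, kind="beta"),
            "t": StatMap(t.reshape(grid), name=name, kind="t"),
        }
    return out


def session_change(week2_map: StatMap, baseline_map: StatMap) -> StatMap:
    """Second level (fixed effects): week-2 minus baseline contrast map."""
    if week2_map.data.shape != baseline_map.data.shape:
        raise ValueError("session maps on different grids")
    return replace(week2_map, data=week2_map.data - baseline_map.data,
                   name=f"{week2_map.name} (week2 > baseline)")


def extract_seed_timecourse(bold: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Mean BOLD series over the voxels of a (nonempty) binary mask."""
    if mask.shape != bold.shape[:-1]:
        raise ValueError("mask grid does not match BOLD grid")
    if not mask.any():
        raise ValueError("empty seed mask")
    return bold[mask.astype(bool)].mean(axis=0)


def build_ppi_design(design: pd.DataFrame, seed_series: np.ndarray) -> pd.DataFrame:
    """Append the physiological regressor and the two PPI interaction
    regressors to a first-level design.

    Interactions are products of the *zero-centred* convolved task
    regressors with the seed series; the PPI contrast of interest is
    (happy x seed) - (fearful x seed).
    """
    seed_series = np.asarray(seed_series, dtype=float)
    if len(seed_series) != len(design):
        raise ValueError("seed series length does not match design rows")
    out = design.copy()
    out["seed"] = seed_series
    for cond in ("happy", "fearful"):
        task = design[cond].to_numpy()
        out[f"ppi_{cond}"] = (task - task.mean()) * seed_series
    # keep intercept last
    cols = [c for c in out.columns if c != "intercept"] + ["intercept"]
    return out[cols]


# --- third level -----------------------------------------------------------

GROUP_COVARIATES = ("hamd_baseline", "age", "gender_female", "medication",
                    "n_itbs_sessions")


def make_group_design(frame: pd.DataFrame, interest: str = "hamd_improvement",
                      covariates: tuple[str, ...] = GROUP_COVARIATES) -> pd.DataFrame:
    """Group design: regressor of interest plus control covariates, all
    de-meaned (mean 0 within 1e-10), and an intercept."""
    X = frame[[interest, *covariates]].astype(float).copy()
    X = X - X.mean()
    X["intercept"] = 1.0
    return X


def _stack_maps(change_maps) -> tuple[np.ndarray, tuple[int, ...]]:
    arrs = [m.data if isinstance(m, StatMap) else np.asarray(m) for m in change_maps]
    grid = arrs[0].shape
    if any(a.shape != grid for a in arrs):
        raise ValueError("change maps on different grids")
    return np.stack([a.reshape(-1) for a in arrs]), grid


def group_glm(change_maps, group_design: pd.DataFrame,
              interest: str | None = None) -> StatMap:
    """Voxelwise mixed-effects-style group GLM (OLS across participants):
    t-map for the regressor of interest adjusted for the covariates."""
    Y, grid = _stack_maps(change_maps)
    n = Y.shape[0]
    if n != len(group_design):
        raise ValueError("one change map per design row required")
    if n <= group_design.shape[1]:
        raise ValueError("n must exceed the number of regressors")
    interest = interest or group_design.columns[0]
    cols = list(group_design.columns)
    c = np.zeros(len(cols))
    c[cols.index(interest)] = 1.0
    _, fitted = _ols_tmaps(Y, group_design.to_numpy(), {"interest": c})
    _, t = fitted["interest"]
    return StatMap(t.reshape(grid), name=f"group t ({interest})", kind="t")


def permutation_maxT(change_maps, group_design: pd.DataFrame,
                     n_perm: int = 1000, seed: int = 0,
                     interest: str | None = None,
                     mask: np.ndarray | None = None) -> dict[str, StatMap]:
    """Max-statistic permutation inference (Freedman-Lane) on the group GLM.

    The regressor of interest is tested by permuting the residuals of the
    reduced (covariates-only) model; family-wise-error corrected p-values
    reference each voxel's observed |t| to the permutation distribution of
    the image-wide maximum |t|.  Returns ``t`` and ``p_fwe`` maps (voxels
    outside ``mask`` are set to NaN / 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    Y, grid = _stack_maps(change_maps)
    n = Y.shape[0]
    if n < 6:
        raise ValueError("too few exchangeable units")
    interest = interest or group_design.columns[0]
    cols = list(group_design.columns)
    j = cols.index(interest)
    X = group_design.to_numpy()
    c = np.zeros(len(cols))
    c[j] = 1.0

    if mask is not None:
        if mask.shape != grid:
            raise ValueError("mask grid does not match map grid")
        vox = mask.reshape(-1).astype(bool)
        if not vox.any():
            raise ValueError("mask has no voxels in common with the maps")
    else:
        vox = np.ones(Y.shape[1], dtype=bool)
    Yv = Y[:, vox]

    Z = np.delete(X, j, axis=1)
    pinv_z = np.linalg.pinv(Z)
    Hz_Y = Z @ (pinv_z @ Yv)
    Rz_Y = Yv - Hz_Y

    pinv_x = np.linalg.pinv(X)
    # pinv tolerates a degenerate covariate (e.g. a constant binary column
    # that de-meaning zeroed out); the regressor of interest stays identified
    xtx_inv = np.linalg.pinv(X.T @ X)
    cvar = float(c @ xtx_inv @ c)
    dof = n - np.linalg.matrix_rank(X)

    def _tstat(Ymat: np.ndarray) -> np.ndarray:
        beta = pinv_x @ Ymat
        resid = Ymat - X @ beta
        sigma2 = (resid**2).sum(axis=0) / dof
        with np.errstate(divide="ignore", invalid="ignore"):
            return (c @ beta) / np.sqrt(cvar * sigma2)

    t_obs = _tstat(Yv)
    rng = np.random.default_rng(seed)
    max_null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        Ystar = Rz_Y[perm] + Hz_Y
        max_null[b] = np.abs(_tstat(Ystar)).max()
    exceed = (max_null[:, None] >= np.abs(t_obs)[None, :]).sum(axis=0)
    p_fwe = (1.0 + exceed) / (n_perm + 1.0)

    t_full = np.full(Y.shape[1], np.nan)
    p_full = np.ones(Y.shape[1])
    t_full[vox] = t_obs
    p_full[vox] = p_fwe
    return {
        "t": StatMap(t_full.reshape(grid), name=f"group t ({interest})", kind="t"),
        "p_fwe": StatMap(p_full.reshape(grid), name=f"FWE p ({interest})",
                         kind="p_fwe"),
    }


def roi_small_volume(change_maps, group_design: pd.DataFrame,
                     masks: dict[str, np.ndarray], n_perm: int = 1000,
                     seed: int = 0, alpha: float = ROI_ALPHA,
                     interest: str | None = None) -> pd.DataFrame:
    """Small-volume max-T permutation inference within each ROI mask.

    The significance threshold defaults to alpha = 0.05/6, Bonferroni over
    the six a-priori ROIs.  Returns one row per ROI with the minimum
    corrected p, peak |t| and a significance flag.
    """
    rows = []
    ss = np.random.SeedSequence(seed)
    for (name, mask), child in zip(masks.items(), ss.spawn(len(masks))):
        res = permutation_maxT(change_maps, group_design, n_perm=n_perm,
                               seed=child, interest=interest, mask=mask)
        inside = mask.reshape(-1).astype(bool)
        p_roi = res["p_fwe"].data.reshape(-1)[inside]
        t_roi = res["t"].data.reshape(-1)[inside]
        p_min = float(p_roi.min())
        rows.append({
            "roi": name, "p_fwe_min": p_min,
            "t_peak": float(t_roi[np.nanargmax(np.abs(t_roi))]),
            "alpha": alpha, "significant": p_min < alpha,
            "n_voxels": int(inside.sum()),
        })
    return pd.DataFrame(rows)
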