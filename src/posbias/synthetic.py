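"""Synthetic-cohort generator.

Individual patient data from emotional-bias treatment studies are rarely
shareable, so every stage of this pipeline is exercised on synthetic cohorts
whose ground truth is known.  The generator emulates, per participant:

* two FERT sessions (baseline and week 2) of 250 trials each, with
  confusion-structured categorical responses and log-normal reaction times;
  a *positivity shift* ``delta`` reallocates error mass from negative to
  positive response categories at the second session, planting a response-
  criterion bias without changing overall accuracy;
* a weekly 17-item HAM-D trajectory following an exponential decay towards
  an asymptote, with responder / non-responder profiles (>= 50% vs < 50%
  expected reduction at week 4);
* optionally, block-design BOLD runs on a small voxel grid with known task
  amplitudes and a condition-specific seed-coupling term for PPI recovery;
* demographic and treatment covariates (age, gender, psychoactive
  medication, number of iTBS sessions received before the second session).

All randomness derives from a single master seed via ``numpy``'s
``SeedSequence`` spawning, so a cohort is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import (
    EMOTIONS,
    EMOTION_INDEX,
    NEGATIVE_EMOTIONS,
    NON_NEUTRAL,
    N_INTENSITIES,
    POSITIVE_EMOTIONS,
    EventSchedule,
    build_event_schedule,
    build_fert_design,
)

__all__ = [
    "ResponseModel",
    "TrajectoryModel",
    "BoldSimSpec",
    "BoldRun",
    "CohortSpec",
    "CohortDataset",
    "simulate_fert_session",
    "simulate_hamd",
    "simulate_bold",
    "simulate_cohort",
    "simulate_prediction_features",
    "simulate_motion",
]

# Confusable-expression pairs: low-intensity members of each pair are easily
# mistaken for one another, which gives misclassifications realistic
# structure (and the misclassification-bias metric a non-degenerate null).
CONFUSABLE_PARTNER = {
    "fear": "surprise",
    "surprise": "fear",
    "anger": "disgust",
    "disgust": "anger",
    "sadness": "neutral",
    "neutral": "sadness",
    "happy": "neutral",
}

_POS_IDX = np.array([EMOTION_INDEX[e] for e in POSITIVE_EMOTIONS])
_NEG_IDX = np.array([EMOTION_INDEX[e] for e in NEGATIVE_EMOTIONS])


class InvalidModelError(ValueError):
    """A simulation model violates its own invariants."""


@dataclass
class ResponseModel:
    """Categorical response model for the FERT.

    ``kernel`` has shape (7, 10, 7): probability over the 7 response
    categories for each true emotion x intensity; the neutral row is
    constant across the intensity axis.  ``rt_median_ms`` / ``rt_sigma``
    parameterise a log-normal reaction-time distribution per true emotion.
    ``positivity_shift`` (delta >= -1) scales error mass on the positive
    response categories {happy, surprise} multiplicatively by (1 + delta),
    compensating on the negative categories so that row sums and correct-
    response probabilities are unchanged.
    """

    kernel: np.ndarray
    rt_median_ms: dict[str, float]
    rt_sigma: dict[str, float]
    positivity_shift: float = 0.0

    @classmethod
    def default(
        cls,
        positivity_shift: float = 0.0,
        floor: float = 1.0 / 7.0,
        ceiling: float = 0.97,
        midpoint: float = 4.5,
        slope: float = 1.8,
        partner_weight: float = 0.45,
        neutral_accuracy: float = 0.80,
    ) -> "ResponseModel":
        """Monotone logistic-accuracy template with confusable-pair errors.

        Accuracy rises logistically with morph intensity from near chance to
        ``ceiling``; a fraction ``partner_weight`` of the error mass goes to
        the confusable partner expression, the rest spreads uniformly over
        the remaining categories.
        """
        kernel = np.zeros((7, N_INTENSITIES, 7))
        for emo in EMOTIONS:
            ei = EMOTION_INDEX[emo]
            for j in range(N_INTENSITIES):
                if emo == "neutral":
                    p_correct = neutral_accuracy
                else:
                    intensity = j + 1
                    p_correct = floor + (ceiling - floor) / (
                        1.0 + np.exp(-(intensity - midpoint) / slope)
                    )
                row = np.zeros(7)
                row[ei] = p_correct
                err = 1.0 - p_correct
                partner = EMOTION_INDEX[CONFUSABLE_PARTNER[emo]]
                row[partner] += partner_weight * err
                others = [k for k in range(7) if k not in (ei, partner)]
                row[others] += (1.0 - partner_weight) * err / len(others)
                kernel[ei, j] = row
        rt_median = {
            "happy": 900.0, "surprise": 980.0, "anger": 1100.0,
            "fear": 1150.0, "sadness": 1120.0, "disgust": 1100.0,
            "neutral": 1000.0,
        }
        rt_sigma = {e: 0.30 for e in EMOTIONS}
        model = cls(kernel=kernel, rt_median_ms=rt_median, rt_sigma=rt_sigma)
        if positivity_shift != 0.0:
            model = model.with_positivity_shift(positivity_shift)
        model.validate()
        return model

    def with_positivity_shift(self, delta: float) -> "ResponseModel":
        """Return a copy whose error mass is shifted towards positive labels.

        For each kernel row the mass on incorrect positive categories is
        multiplied by (1 + delta) and the incorrect negative categories are
        scaled down by the same total, so the diagonal (accuracy) and the
        neutral column are untouched.  The transfer is capped so no
        probability goes negative; delta = 0 is the identity.
        """
        if delta < -1.0:
            raise InvalidModelError("positivity_shift must be >= -1")
        kernel = self.kernel.copy()
        for ei in range(7):
            for j in range(N_INTENSITIES):
                row = kernel[ei, j]
                pos = np.setdiff1d(_POS_IDX, [ei])
                neg = np.setdiff1d(_NEG_IDX, [ei])
                m_pos = row[pos].sum()
                m_neg = row[neg].sum()
                if m_pos <= 0 or m_neg <= 0:
                    continue
                transfer = delta * m_pos
                transfer = min(transfer, m_neg)       # cannot overdraw negatives
                transfer = max(transfer, -m_pos)      # nor positives
                row[pos] *= 1.0 + transfer / m_pos
                row[neg] *= 1.0 - transfer / m_neg
        out = replace(self, kernel=kernel, positivity_shift=delta)
        out.validate()
        return out

    def validate(self) -> None:
        if self.kernel.shape != (7, N_INTENSITIES, 7):
            raise InvalidModelError(f"kernel shape {self.kernel.shape}")
        sums = self.kernel.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-12):
            raise InvalidModelError("kernel rows must sum to 1 within 1e-12")
        if (self.kernel < -1e-15).any():
            raise InvalidModelError("negative kernel probability")
        missing = set(EMOTIONS) - set(self.rt_median_ms) | set(EMOTIONS) - set(self.rt_sigma)
        if missing:
            raise InvalidModelError(f"rt model missing emotions: {sorted(missing)}")


_EMOTION_ARRAY = np.array(EMOTIONS)


def _design_codes(design: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    emo_idx = pd.Categorical(design.true_emotion, categories=EMOTIONS).codes
    int_idx = np.maximum(design.intensity.to_numpy() - 1, 0)  # neutral -> row 0
    return emo_idx.astype(np.intp), int_idx.astype(np.intp)


def simulate_fert_session(
    design: pd.DataFrame, model: ResponseModel, seed: int | np.random.SeedSequence
) -> pd.DataFrame:
    """Simulate responses and reaction times for one FERT session.

    Responses are drawn per trial from the model's confusion kernel by
    inverse-CDF sampling (category order = canonical emotion order, so under
    common random numbers a larger positivity shift can only move responses
    towards positive labels).  Reaction times are log-normal per true
    emotion.  Returns the design with ``response_emotion``, ``rt_ms`` and
    ``correct`` columns appended.
    """
    model.validate()
    rng = np.random.default_rng(seed)
    emo_idx, int_idx = _design_codes(design)
    probs = model.kernel[emo_idx, int_idx]
    cum = probs.cumsum(axis=1)
    u = rng.random(len(design))
    resp_idx = np.minimum((u[:, None] > cum).sum(axis=1), 6)
    log_med = np.log([model.rt_median_ms[e] for e in EMOTIONS])
    sig = np.array([model.rt_sigma[e] for e in EMOTIONS])
    rt = np.exp(rng.normal(log_med[emo_idx], sig[emo_idx]))
    out = design.copy()
    out["response_emotion"] = _EMOTION_ARRAY[resp_idx]
    out["rt_ms"] = rt
    out["correct"] = resp_idx == emo_idx
    return out


# --- HAM-D trajectories ----------------------------------------------------

HAMD_MAX = 52
INCLUSION_FLOOR = 14


@dataclass
class TrajectoryModel:
    """Exponential-decay HAM-D profile: s(t) = s_inf + (s0 - s_inf) e^{-kt}."""

    s0: float
    s_inf: float
    k: float
    noise_sd: float = 0.0

    def validate(self) -> None:
        if self.k < 0:
            raise InvalidModelError("decay rate k must be >= 0")
        if self.s0 < INCLUSION_FLOOR:
            raise InvalidModelError(f"baseline below inclusion floor {INCLUSION_FLOOR}")

    def expected(self, weeks: np.ndarray) -> np.ndarray:
        weeks = np.asarray(weeks, dtype=float)
        with np.errstate(invalid="ignore", over="ignore"):
            decay = np.exp(-self.k * weeks)
        decay = np.where(weeks == 0, 1.0, decay)   # covers k = inf at t = 0
        return self.s_inf + (self.s0 - self.s_inf) * decay


def simulate_hamd(
    model: TrajectoryModel,
    weeks: list[int] | np.ndarray,
    seed: int | np.random.SeedSequence,
) -> pd.DataFrame:
    """Simulate a weekly HAM-D series; scores are clipped to [0, 52]."""
    weeks = np.asarray(weeks)
    if weeks.size == 0 or (weeks < 0).any():
        raise ValueError("weeks must be nonempty and nonnegative")
    model.validate()
    rng = np.random.default_rng(seed)
    scores = model.expected(weeks) + rng.normal(0.0, model.noise_sd, size=weeks.size)
    scores = np.clip(np.round(scores), 0, HAMD_MAX).astype(int)
    return pd.DataFrame({"week": weeks, "score": scores})


# --- BOLD simulation -------------------------------------------------------


def _cube_mask(grid: tuple[int, int, int], corner, size) -> np.ndarray:
    m = np.zeros(grid, dtype=bool)
    sl = tuple(slice(c, c + size) for c in corner)
    m[sl] = True
    return m


@dataclass
class BoldSimSpec:
    """Generating model for one block-design BOLD run on a small grid.

    Voxels in ``active_mask`` and ``seed_mask`` carry task signal
    ``beta_happy * X_happy + beta_fear * X_fear`` (HRF-convolved block
    regressors).  Seed voxels additionally carry a smooth latent fluctuation
    eta(t); ``target_mask`` voxels receive ``coupling * eta(t)`` scaled by
    ``ppi_gain`` during happy blocks, i.e. condition-specific functional
    coupling with the seed.  ``ppi_gain = 1`` means no condition dependence.
    Gaussian noise of ``noise_sd`` is added everywhere; the latent sd
    defaults to ``2 * noise_sd`` so a noiseless spec yields noiseless data.
    """

    grid_dims: tuple[int, int, int] = (8, 8, 8)
    events: EventSchedule = field(default_factory=build_event_schedule)
    seed_mask: np.ndarray | None = None
    target_mask: np.ndarray | None = None
    active_mask: np.ndarray | None = None
    beta_happy: float = 1.0
    beta_fear: float = 1.0
    ppi_gain: float = 1.0
    coupling: float = 0.7
    noise_sd: float = 0.5
    latent_sd: float | None = None
    latent_ar: float = 0.6

    def __post_init__(self) -> None:
        g = tuple(self.grid_dims)
        if self.seed_mask is None:
            self.seed_mask = _cube_mask(g, (1, 1, 1), 2)
        if self.target_mask is None:
            self.target_mask = _cube_mask(g, (g[0] - 3, g[1] - 3, g[2] - 3), 2)
        if self.active_mask is None:
            self.active_mask = _cube_mask(g, (1, g[1] - 3, 1), 2)

    @property
    def tr(self) -> float:
        return self.events.tr

    @property
    def n_volumes(self) -> int:
        return self.events.n_volumes

    def validate(self) -> None:
        g = tuple(self.grid_dims)
        for name, m in (("seed_mask", self.seed_mask),
                        ("target_mask", self.target_mask),
                        ("active_mask", self.active_mask)):
            if m.shape != g:
                raise ValueError(f"{name} shape {m.shape} != grid {g}")
        if not self.seed_mask.any():
            raise ValueError("seed_mask is empty")
        self.events.validate()
        ev = self.events
        if len(ev.face_events("happy")) != 120 or len(ev.face_events("fearful")) != 120:
            raise ValueError("schedule must contain 120 happy and 120 fearful faces")
        if ev.n_fixation_blocks != 9:
            raise ValueError("schedule must contain 9 fixation blocks")


@dataclass
class BoldRun:
    """One simulated BOLD run: data (x, y, z, t), events and motion params."""

    data: np.ndarray
    events: EventSchedule
    motion: np.ndarray


def simulate_motion(
    n_volumes: int,
    seed: int | np.random.SeedSequence,
    step_sd: float = 0.01,
    smooth: int = 10,
) -> np.ndarray:
    """Six smooth low-amplitude random walks (3 rotations, 3 translations)."""
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, step_sd, size=(n_volumes + smooth, 6))
    walk = np.cumsum(steps, axis=0)
    kern = np.ones(smooth) / smooth
    sm = np.column_stack([np.convolve(walk[:, j], kern, mode="same") for j in range(6)])
    return sm[:n_volumes]


def _block_indicator(events: EventSchedule, condition: str) -> np.ndarray:
    """0/1 indicator at the TR grid of being inside a block of `condition`."""
    t = np.arange(events.n_volumes) * events.tr
    ind = np.zeros(events.n_volumes)
    faces = events.face_events(condition)
    if len(faces) == 0:
        return ind
    # group contiguous faces into blocks via gaps > 2 s
    onsets = faces.onset.to_numpy()
    gaps = np.where(np.diff(onsets) > 2.0)[0]
    starts = np.concatenate([[onsets[0]], onsets[gaps + 1]])
    ends = np.concatenate([onsets[gaps], [onsets[-1]]]) + 1.0
    for s, e in zip(starts, ends):
        ind[(t >= s) & (t < e)] = 1.0
    return ind


def simulate_bold(spec: BoldSimSpec, seed: int | np.random.SeedSequence) -> BoldRun:
    """Simulate one BOLD run from the generating model in ``spec``."""
    from .glm import task_regressors  # deferred: glm also stands alone

    spec.validate()
    rng = np.random.default_rng(seed)
    xh, xf = task_regressors(spec.events)
    nv = spec.n_volumes
    latent_sd = 2.0 * spec.noise_sd if spec.latent_sd is None else spec.latent_sd
    eps = rng.normal(0.0, 1.0, nv)
    eta = np.empty(nv)
    acc = 0.0
    for i in range(nv):
        acc = spec.latent_ar * acc + eps[i]
        eta[i] = acc
    eta *= latent_sd * np.sqrt(1.0 - spec.latent_ar**2)
    task = spec.beta_happy * xh + spec.beta_fear * xf
    block_h = _block_indicator(spec.events, "happy")
    data = rng.normal(0.0, spec.noise_sd, size=(*spec.grid_dims, nv))
    data[spec.active_mask] += task
    data[spec.seed_mask] += task + eta
    target_sig = spec.coupling * eta * (1.0 + (spec.ppi_gain - 1.0) * block_h)
    data[spec.target_mask] += target_sig
    motion = simulate_motion(nv, rng.integers(2**31))
    return BoldRun(data=data, events=spec.events, motion=motion)


# --- full cohort -----------------------------------------------------------

SESSIONS = ("baseline", "week2")
HAMD_WEEKS = (0, 1, 2, 3, 4, 5, 6)


@dataclass
class CohortSpec:
    """Study conditions for a simulated cohort.

    Defaults mirror the treatment-study design this pipeline targets:
    n = 49 with a 33/16 responder / non-responder split, two FERT sessions,
    weekly HAM-D over weeks 0-6, and covariates distributed as in the trial
    sample (41/49 female, 30/49 medicated, 7-10 iTBS sessions before the
    week-2 assessment with modal 8).  The positivity shift applied to the
    week-2 FERT session of responders defaults to the value calibrated to
    plant a standardised misclassification-bias effect of about d = 1.3.
    """

    n: int = 49
    responder_fraction: float = 33.0 / 49.0
    delta_responder: float = 0.335
    delta_nonresponder: float = 0.0
    hamd_noise_sd: float = 1.0
    age_mean: float = 39.2
    age_sd: float = 10.4
    p_female: float = 41.0 / 49.0
    p_medication: float = 30.0 / 49.0
    itbs_session_probs: tuple[float, ...] = (4 / 49, 37 / 49, 4 / 49, 4 / 49)
    bold: BoldSimSpec | None = None
    master_seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction must be in [0, 1]")
        if self.n < 2:
            raise ValueError("need n >= 2")


@dataclass
class CohortDataset:
    """A bundled synthetic study standing in for the (unshareable) trial."""

    spec: CohortSpec
    participants: pd.DataFrame
    fert: dict[tuple[str, str], pd.DataFrame]
    hamd: pd.DataFrame
    bold: dict[tuple[str, str], BoldRun]

    @property
    def ids(self) -> list[str]:
        return list(self.participants.participant_id)


def _responder_trajectory(rng: np.random.Generator, responder: bool, noise_sd: float) -> TrajectoryModel:
    if responder:
        s0 = max(INCLUSION_FLOOR, rng.normal(18.3, 2.8))
        frac = np.clip(rng.normal(0.70, 0.06), 0.60, 0.92)
        k = rng.uniform(0.5, 1.0)
    else:
        s0 = max(INCLUSION_FLOOR, rng.normal(17.6, 2.3))
        frac = np.clip(rng.normal(0.22, 0.08), 0.02, 0.36)
        k = rng.uniform(0.3, 0.8)
    s4 = s0 * (1.0 - frac)
    decay4 = np.exp(-4.0 * k)
    s_inf = (s4 - s0 * decay4) / (1.0 - decay4)
    return TrajectoryModel(s0=s0, s_inf=s_inf, k=k, noise_sd=noise_sd)


def simulate_cohort(spec: CohortSpec | None = None) -> CohortDataset:
    """Simulate a full cohort: FERT x 2, HAM-D weeks 0-6, covariates and,
    when ``spec.bold`` is set, two BOLD runs per participant.

    The week-2 FERT session of each participant receives the positivity
    shift of their (ground-truth) response class; the baseline session is
    always generated at delta = 0.
    """
    spec = spec or CohortSpec()
    spec.validate()
    n_resp = int(round(spec.n * spec.responder_fraction))
    n_resp = min(max(n_resp, 1), spec.n - 1)
    classes = ["responder"] * n_resp + ["non-responder"] * (spec.n - n_resp)

    ss = np.random.SeedSequence(spec.master_seed)
    part_seeds = ss.spawn(spec.n)
    base_model = ResponseModel.default()
    shifted = {
        "responder": base_model.with_positivity_shift(spec.delta_responder),
        "non-responder": base_model.with_positivity_shift(spec.delta_nonresponder),
    }

    rows = []
    fert: dict[tuple[str, str], pd.DataFrame] = {}
    bold: dict[tuple[str, str], BoldRun] = {}
    hamd_frames = []
    for i, (cls, pseed) in enumerate(zip(classes, part_seeds)):
        pid = f"sub-{i + 1:03d}"
        (s_cov, s_traj, s_des0, s_des1, s_f0, s_f1, s_b0, s_b1) = pseed.spawn(8)
        rng = np.random.default_rng(s_cov)
        age = float(np.clip(rng.normal(spec.age_mean, spec.age_sd), 18, 65))
        gender = "F" if rng.random() < spec.p_female else "M"
        medication = bool(rng.random() < spec.p_medication)
        n_itbs = int(rng.choice([7, 8, 9, 10], p=spec.itbs_session_probs))

        traj = _responder_trajectory(np.random.default_rng(s_traj), cls == "responder",
                                     spec.hamd_noise_sd)
        series = simulate_hamd(traj, list(HAMD_WEEKS), s_traj.spawn(1)[0])
        series.insert(0, "participant_id", pid)
        hamd_frames.append(series)

        d0 = build_fert_design(int(np.random.default_rng(s_des0).integers(2**31)))
        d1 = build_fert_design(int(np.random.default_rng(s_des1).integers(2**31)))
        fert[(pid, "baseline")] = simulate_fert_session(d0, base_model, s_f0)
        fert[(pid, "week2")] = simulate_fert_session(d1, shifted[cls], s_f1)

        if spec.bold is not None:
            bold[(pid, "baseline")] = simulate_bold(spec.bold, s_b0)
            bold[(pid, "week2")] = simulate_bold(spec.bold, s_b1)

        rows.append({
            "participant_id": pid, "true_class": cls, "age": age,
            "gender": gender, "medication": medication,
            "n_itbs_sessions": n_itbs,
        })

    participants = pd.DataFrame(rows)
    hamd = pd.concat(hamd_frames, ignore_index=True)
    return CohortDataset(spec=spec, participants=participants, fert=fert,
                        hamd=hamd, bold=bold)


# --- feature simulator for predictive-model experiments --------------------


def simulate_prediction_features(
    n: int = 49,
    n_bias: int = 3,
    partial_r2_bias: float = 0.3,
    clinical_r2: float = 0.25,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Simulate (clinical features, augmented features, outcome) for the
    "does early bias change add predictive signal" experiment.

    The outcome loads on early symptom change (clinical signal) and on a
    latent bias factor measured by ``n_bias`` noisy proxy features;
    ``partial_r2_bias`` is the population fraction of outcome variance not
    explained by the clinical block that the *observed* bias features carry
    (the latent loading is inflated to undo proxy-measurement attenuation).
    Setting it to 0 makes the bias features pure noise.
    """
    rng = np.random.default_rng(seed)
    early_change = rng.normal(0.0, 1.0, n)
    baseline_hamd = rng.normal(18.0, 2.7, n)
    age = rng.normal(39.0, 10.0, n)
    gender = (rng.random(n) < 41 / 49).astype(float)
    medication = (rng.random(n) < 30 / 49).astype(float)

    u = rng.normal(0.0, 1.0, n)
    sigma2 = 1.0
    proxy_sd = 0.8
    if partial_r2_bias > 0:
        # multiple R^2 of the latent factor on its n_bias proxies
        r2_u = (n_bias / proxy_sd**2) / (n_bias / proxy_sd**2 + 1.0)
        if partial_r2_bias >= r2_u:
            raise ValueError("partial_r2_bias unattainable with these proxies")
        gamma2 = partial_r2_bias * sigma2 / (r2_u - partial_r2_bias)
    else:
        gamma2 = 0.0
    alpha2 = clinical_r2 * (gamma2 + sigma2) / (1.0 - clinical_r2)
    y = (np.sqrt(alpha2) * early_change + np.sqrt(gamma2) * u
         + rng.normal(0.0, np.sqrt(sigma2), n))

    clinical = pd.DataFrame({
        "early_hamd_change": early_change,
        "baseline_hamd": baseline_hamd,
        "age": age,
        "gender": gender,
        "medication": medication,
    })
    bias = pd.DataFrame({
        f"bias_change_{j + 1}": u + rng.normal(0.0, proxy_sd, n) if partial_r2_bias > 0
        else rng.normal(0.0, 1.0, n)
        for j in range(n_bias)
    })
    augmented = pd.concat([clinical, bias], axis=1)
    return clinical, augmented, y
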