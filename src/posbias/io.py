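"""File formats and input validation.

Tables travel as tidy CSV/TSV with header contracts, event schedules as
BIDS-style events TSV (onset, duration, trial_type), volumes and masks as
NIfTI (via nibabel), motion parameters as 6-column whitespace text, and
result bundles as JSON.  Floating-point output is written with 12
significant digits so rerun checksums are meaningful.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .design import EMOTIONS, EventSchedule

FLOAT_FORMAT = "%.12g"

TRIAL_COLUMNS = ("true_emotion", "intensity", "actor", "response_emotion",
                 "rt_ms", "correct")
HAMD_COLUMNS = ("participant_id", "week", "score")
COVARIATE_COLUMNS = ("participant_id", "age", "gender", "medication",
                     "n_itbs_sessions")


def write_table(df: pd.DataFrame, path: Path) -> Path:
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df.to_csv(path, sep=sep, index=False, float_format=FLOAT_FORMAT)
    return path


def read_table(path: Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    return pd.read_csv(path, sep=sep)


def write_events(schedule: EventSchedule, path: Path) -> Path:
    return write_table(schedule.events, Path(path))


def read_events(path: Path, tr: float, n_volumes: int) -> EventSchedule:
    ev = read_table(path)
    sched = EventSchedule(events=ev, tr=tr, n_volumes=n_volumes)
    sched.validate()
    return sched


def write_volume(data: np.ndarray, path: Path,
                 affine: np.ndarray | None = None) -> Path:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32),
                          np.eye(4) if affine is None else affine)
    nib.save(img, str(path))
    return Path(path)


def read_volume(path: Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def write_motion(motion: np.ndarray, path: Path) -> Path:
    np.savetxt(path, motion, fmt=FLOAT_FORMAT)
    return Path(path)


def read_motion(path: Path) -> np.ndarray:
    return np.loadtxt(path).reshape(-1, 6)


def write_json(obj, path: Path) -> Path:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")
    return Path(path)


def sha256_of(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# --- cohort round-trip -----------------------------------------------------


def write_cohort(cohort, out_dir: Path) -> None:
    """Write a CohortDataset to a directory (tables as CSV, runs as NIfTI,
    a JSON manifest with the generating parameters)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(cohort.participants, out / "covariates.csv")
    write_table(cohort.hamd, out / "hamd.csv")
    fert_dir = out / "fert"
    fert_dir.mkdir(exist_ok=True)
    for (pid, session), trials in cohort.fert.items():
        write_table(trials, fert_dir / f"{pid}_{session}.csv")
    spec = cohort.spec
    meta = {
        "n": spec.n, "responder_fraction": spec.responder_fraction,
        "delta_responder": spec.delta_responder,
        "delta_nonresponder": spec.delta_nonresponder,
        "master_seed": spec.master_seed,
        "bold": None,
    }
    if cohort.bold:
        b = spec.bold
        meta["bold"] = {"grid_dims": list(b.grid_dims), "tr": b.tr,
                        "n_volumes": b.n_volumes, "noise_sd": b.noise_sd,
                        "ppi_gain": b.ppi_gain, "beta_happy": b.beta_happy,
                        "beta_fear": b.beta_fear}
        bold_dir = out / "bold"
        bold_dir.mkdir(exist_ok=True)
        any_run = next(iter(cohort.bold.values()))
        write_events(any_run.events, bold_dir / "events.tsv")
        for name in ("seed_mask", "target_mask", "active_mask"):
            write_volume(getattr(b, name).astype(float), bold_dir / f"{name}.nii")
        for (pid, session), run in cohort.bold.items():
            write_volume(run.data, bold_dir / f"{pid}_{session}.nii")
            write_motion(run.motion, bold_dir / f"{pid}_{session}_motion.txt")
    write_json(meta, out / "cohort_meta.json")


def read_cohort(out_dir: Path):
    """Reload a cohort written by :func:`write_cohort`."""
    from .synthetic import BoldRun, BoldSimSpec, CohortDataset, CohortSpec

    out = Path(out_dir)
    meta = json.loads((out / "cohort_meta.json").read_text())
    participants = read_table(out / "covariates.csv")
    hamd = read_table(out / "hamd.csv")
    fert = {}
    for path in sorted((out / "fert").glob("*.csv")):
        pid, _, session = path.stem.rpartition("_")
        fert[(pid, session)] = read_table(path)
    bold = {}
    bold_spec = None
    if meta.get("bold"):
        b = meta["bold"]
        bold_dir = out / "bold"
        events = read_events(bold_dir / "events.tsv", tr=b["tr"],
                             n_volumes=b["n_volumes"])
        masks = {name: read_volume(bold_dir / f"{name}.nii")[0] > 0.5
                 for name in ("seed_mask", "target_mask", "active_mask")}
        bold_spec = BoldSimSpec(
            grid_dims=tuple(b["grid_dims"]), events=events,
            noise_sd=b["noise_sd"], ppi_gain=b["ppi_gain"],
            beta_happy=b["beta_happy"], beta_fear=b["beta_fear"], **masks)
        for path in sorted(bold_dir.glob("sub-*.nii")):
            pid, _, session = path.stem.rpartition("_")
            data, _ = read_volume(path)
            motion = read_motion(bold_dir / f"{pid}_{session}_motion.txt")
            bold[(pid, session)] = BoldRun(data=data, events=events, motion=motion)
    spec = CohortSpec(
        n=meta["n"], responder_fraction=meta["responder_fraction"],
        delta_responder=meta["delta_responder"],
        delta_nonresponder=meta["delta_nonresponder"],
        bold=bold_spec, master_seed=meta["master_seed"])
    return CohortDataset(spec=spec, participants=participants, fert=fert,
                         hamd=hamd, bold=bold)


# --- validation ------------------------------------------------------------


def _check_columns(df: pd.DataFrame, required, label: str, issues: list) -> bool:
    missing = [c for c in required if c not in df.columns]
    if missing:
        issues.append(f"{label}: missing columns {missing}")
        return False
    return True


def validate_trial_table(df: pd.DataFrame, label: str = "trials") -> list[str]:
    issues: list[str] = []
    if not _check_columns(df, TRIAL_COLUMNS, label, issues):
        return issues
    bad_emo = df.loc[~df.true_emotion.isin(EMOTIONS)]
    for i in bad_emo.index:
        issues.append(f"{label}: row {i}: unknown true_emotion "
                      f"{df.loc[i, 'true_emotion']!r}")
    resp = df.response_emotion.dropna()
    for i in resp[~resp.isin(EMOTIONS)].index:
        issues.append(f"{label}: row {i}: unknown response_emotion "
                      f"{df.loc[i, 'response_emotion']!r}")
    for i in df.index[df.rt_ms <= 0]:
        issues.append(f"{label}: row {i}: non-positive rt_ms")
    return issues


def validate_hamd_table(df: pd.DataFrame, label: str = "hamd") -> list[str]:
    issues: list[str] = []
    if not _check_columns(df, HAMD_COLUMNS, label, issues):
        return issues
    scores = df.score.dropna()
    for i in scores[(scores < 0) | (scores > 52)].index:
        issues.append(f"{label}: row {i}: score outside [0, 52]")
    for pid, grp in df.groupby("participant_id"):
        if 0 not in set(grp.week):
            issues.append(f"{label}: participant {pid}: week 0 missing")
    return issues


def validate_inputs(trials: pd.DataFrame | None = None,
                    hamd: pd.DataFrame | None = None,
                    bold_shape: tuple | None = None,
                    mask_shape: tuple | None = None) -> list[str]:
    """Schema checks across the pipeline inputs; issues are itemised
    strings, empty list = all well-formed."""
    issues: list[str] = []
    if trials is not None:
        issues += validate_trial_table(trials)
    if hamd is not None:
        issues += validate_hamd_table(hamd)
    if bold_shape is not None and mask_shape is not None:
        if tuple(bold_shape[:3]) != tuple(mask_shape):
            issues.append(
                f"grid mismatch: BOLD grid {tuple(bold_shape[:3])} "
                f"!= mask grid {tuple(mask_shape)}")
    return issues
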