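"""Pipeline orchestration: configuration, staged execution, run manifest.

``run_pipeline`` executes the stages in dependency order on a synthetic (or
user-supplied) cohort:

    simulate -> score -> outcomes -> group_stats -> glm (incl. PPI) -> compare

Each stage writes its outputs under ``out_dir`` and records checksums in a
run manifest; rerunning with an identical configuration skips stages whose
outputs already exist (config-hash guarded), so partial runs resume.
Configuration is a strict YAML mapping — unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import glm as glm_mod
from . import io as pio
from .fert import METRICS
from .inference import (
    analysis_frame_from_cohort,
    baseline_table,
    bonferroni,
    cohens_d,
    linear_predict_improvement,
    logistic_predict_response,
    mixed_anova_time_by_response,
)
from .model_comparison import compare_models
from .outcomes import outcomes_table
from .synthetic import BoldSimSpec, CohortSpec, simulate_cohort

STAGES = ("simulate", "score", "outcomes", "group_stats", "glm", "compare")


class ConfigError(ValueError):
    """Invalid pipeline configuration (unknown key, bad value)."""


@dataclass
class BoldConfig:
    enabled: bool = False
    grid: tuple[int, int, int] = (8, 8, 8)
    noise_sd: float = 0.5
    ppi_gain: float = 2.0
    beta_happy: float = 1.0
    beta_fear: float = 1.0


@dataclass
class CohortConfig:
    n: int = 49
    responder_fraction: float = 33.0 / 49.0
    delta_responder: float = 0.335
    delta_nonresponder: float = 0.0
    bold: BoldConfig = field(default_factory=BoldConfig)


@dataclass
class HrfConfig:
    lag: float = 6.0
    dispersion: float = 3.0


@dataclass
class PermutationConfig:
    n_perm: int = 200


@dataclass
class CvConfig:
    k_outer: int = 5
    k_inner: int = 5
    l1_ratios: tuple[float, ...] = (0.1, 0.5, 0.9)
    n_alphas: int = 20


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "scratch/run"
    stages: tuple[str, ...] = STAGES
    cohort: CohortConfig = field(default_factory=CohortConfig)
    hrf: HrfConfig = field(default_factory=HrfConfig)
    permutation: PermutationConfig = field(default_factory=PermutationConfig)
    cv: CvConfig = field(default_factory=CvConfig)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        return _build(cls, raw, path="config")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")


def _build(cls, raw: dict, path: str):
    """Construct a (nested) dataclass from a mapping, rejecting unknown keys."""
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(raw) - set(fields)
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")
    kwargs = {}
    for name, value in raw.items():
        sub = {"cohort": CohortConfig, "bold": BoldConfig, "hrf": HrfConfig,
               "permutation": PermutationConfig, "cv": CvConfig}.get(name)
        if sub is not None:
            kwargs[name] = _build(sub, value, f"{path}.{name}")
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stages_run: list[str] = field(default_factory=list)
    stages_skipped: list[str] = field(default_factory=list)
    checksums: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    started: str = ""
    finished: str = ""

    def record(self, path: Path, root: Path) -> None:
        self.checksums[str(path.relative_to(root))] = pio.sha256_of(path)


def _cohort_spec(cfg: PipelineConfig) -> CohortSpec:
    bold = None
    if cfg.cohort.bold.enabled:
        bold = BoldSimSpec(
            grid_dims=tuple(cfg.cohort.bold.grid),
            noise_sd=cfg.cohort.bold.noise_sd,
            ppi_gain=cfg.cohort.bold.ppi_gain,
            beta_happy=cfg.cohort.bold.beta_happy,
            beta_fear=cfg.cohort.bold.beta_fear,
        )
    return CohortSpec(
        n=cfg.cohort.n,
        responder_fraction=cfg.cohort.responder_fraction,
        delta_responder=cfg.cohort.delta_responder,
        delta_nonresponder=cfg.cohort.delta_nonresponder,
        bold=bold,
        master_seed=cfg.seed,
    )


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run the configured stages end-to-end; returns the run manifest
    (also written to ``out_dir/manifest.json``)."""
    from . import __version__

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.config_hash(),
                           version=__version__,
                           started=time.strftime("%Y-%m-%dT%H:%M:%S"))
    prior = _load_prior_manifest(out)
    resumable = prior is not None and prior.get("config_hash") == manifest.config_hash

    cohort = None

    def _need_cohort():
        nonlocal cohort
        if cohort is None:
            if resumable and (out / "cohort_meta.json").exists():
                cohort = pio.read_cohort(out)
            else:
                cohort = simulate_cohort(_cohort_spec(config))
        return cohort

    # --- simulate ---------------------------------------------------------
    if "simulate" in config.stages:
        if resumable and (out / "cohort_meta.json").exists():
            manifest.stages_skipped.append("simulate")
        else:
            pio.write_cohort(_need_cohort(), out)
            # reload so downstream stages always score the serialised data:
            # reruns resumed from disk then reproduce identical checksums
            cohort = pio.read_cohort(out)
            manifest.stages_run.append("simulate")
            manifest.record(out / "covariates.csv", out)
            manifest.record(out / "hamd.csv", out)

    # --- score + outcomes + frame ----------------------------------------
    frame = None
    if {"score", "outcomes", "group_stats", "glm", "compare"} & set(config.stages):
        frame = analysis_frame_from_cohort(_need_cohort())
    if "score" in config.stages:
        cols = (["participant_id"]
                + [f"{m}_{s}" for m in METRICS for s in ("baseline", "week2", "delta")])
        pio.write_table(frame[cols], out / "bias_scores.csv")
        manifest.stages_run.append("score")
        manifest.record(out / "bias_scores.csv", out)
    if "outcomes" in config.stages:
        tab = outcomes_table(_need_cohort().hamd)
        pio.write_table(tab, out / "outcomes.csv")
        if tab.imputed.any():
            manifest.warnings.append(
                f"week-4 imputation used for {int(tab.imputed.sum())} participant(s)")
        manifest.stages_run.append("outcomes")
        manifest.record(out / "outcomes.csv", out)

    # --- group statistics -------------------------------------------------
    if "group_stats" in config.stages:
        results = {}
        pvals = {}
        for m in METRICS:
            res = mixed_anova_time_by_response(frame, m)
            pvals[m] = res.p
            logit = logistic_predict_response(frame, m)
            ols = linear_predict_improvement(frame, f"{m}_delta")
            x = frame.loc[frame.response == "responder", f"{m}_delta"].dropna()
            y = frame.loc[frame.response == "non-responder", f"{m}_delta"].dropna()
            d = cohens_d(x, y)
            if logit.extras["method"] == "firth":
                manifest.warnings.append(f"{m}: logistic fit fell back to Firth")
            results[m] = {
                "interaction_F": res.statistic, "interaction_df": res.df,
                "interaction_p": res.p,
                "logistic_beta": logit.extras["beta"], "logistic_z": logit.statistic,
                "logistic_p": logit.p, "odds_ratio": logit.effect,
                "odds_ratio_ci": logit.effect_ci,
                "odds_ratio_per_sd": logit.extras["odds_ratio_per_sd"],
                "linear_beta": ols.effect, "linear_t": ols.statistic,
                "linear_p": ols.p,
                "cohens_d": d.effect, "cohens_d_ci": d.effect_ci,
            }
        corrected = bonferroni([pvals[m] for m in METRICS], m=len(METRICS))
        for m, pc in zip(METRICS, corrected):
            results[m]["interaction_p_corrected"] = float(pc)
        results["baseline_table"] = baseline_table(frame).to_dict("records")
        pio.write_json(results, out / "group_stats.json")
        manifest.stages_run.append("group_stats")
        manifest.record(out / "group_stats.json", out)

    # --- GLM / PPI --------------------------------------------------------
    if "glm" in config.stages and config.cohort.bold.enabled:
        c = _need_cohort()
        spec = c.spec.bold
        change_task, change_ppi = [], []
        for pid in c.ids:
            per_session = {}
            for session in ("baseline", "week2"):
                run = c.bold[(pid, session)]
                design = glm_mod.build_design(run.events, run.motion,
                                              hrf_lag=config.hrf.lag,
                                              hrf_dispersion=config.hrf.dispersion)
                maps = glm_mod.fit_first_level(run.data, design,
                                               contrasts=("happy_gt_fearful",))
                seed_tc = glm_mod.extract_seed_timecourse(run.data, spec.seed_mask)
                ppi_maps = glm_mod.fit_first_level(
                    run.data, glm_mod.build_ppi_design(design, seed_tc),
                    contrasts=("happy_gt_fearful",))
                per_session[session] = (maps["happy_gt_fearful"]["beta"],
                                        ppi_maps["ppi_happy_gt_fearful"]["beta"])
            change_task.append(glm_mod.session_change(per_session["week2"][0],
                                                      per_session["baseline"][0]))
            change_ppi.append(glm_mod.session_change(per_session["week2"][1],
                                                     per_session["baseline"][1]))
        gd = glm_mod.make_group_design(frame)
        res_task = glm_mod.permutation_maxT(change_task, gd,
                                            n_perm=config.permutation.n_perm,
                                            seed=config.seed + 1)
        res_ppi = glm_mod.permutation_maxT(change_ppi, gd,
                                           n_perm=config.permutation.n_perm,
                                           seed=config.seed + 2)
        glm_dir = out / "glm"
        glm_dir.mkdir(exist_ok=True)
        for tag, res in (("task", res_task), ("ppi", res_ppi)):
            pio.write_volume(res["t"].data, glm_dir / f"group_{tag}_t.nii")
            pio.write_volume(res["p_fwe"].data, glm_dir / f"group_{tag}_p_fwe.nii")
            manifest.record(glm_dir / f"group_{tag}_t.nii", out)
        manifest.stages_run.append("glm")

    # --- model comparison -------------------------------------------------
    if "compare" in config.stages:
        hamd = _need_cohort().hamd.pivot(index="participant_id", columns="week",
                                         values="score")
        fr = frame.set_index("participant_id")
        feats = pd.DataFrame({
            "early_hamd_change": (hamd[0] - hamd[2]).reindex(fr.index),
            "baseline_hamd": fr.hamd_baseline,
            "age": fr.age,
            "gender": fr.gender_female,
            "medication": fr.medication,
        })
        bias = fr[["pb_misclass_delta"]]
        ok = feats.notna().all(axis=1) & bias.notna().all(axis=1)
        rep = compare_models(feats[ok], pd.concat([feats, bias], axis=1)[ok],
                             fr.hamd_improvement[ok].to_numpy(),
                             k_outer=config.cv.k_outer, k_inner=config.cv.k_inner,
                             seed=config.seed,
                             l1_ratios=config.cv.l1_ratios,
                             n_alphas=config.cv.n_alphas)
        pio.write_json(rep.to_dict(), out / "model_comparison.json")
        manifest.stages_run.append("compare")
        manifest.record(out / "model_comparison.json", out)

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    pio.write_json(dataclasses.asdict(manifest), out / "manifest.json")
    return manifest


def _load_prior_manifest(out: Path) -> dict | None:
    p = out / "manifest.json"
    if p.exists():
        try:
            return json.loads(p.read_text())
        except json.JSONDecodeError:
            return None
    return None
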