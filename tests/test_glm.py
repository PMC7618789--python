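"""GLM/PPI engine: HRF, design construction, first-level estimation,
session change, seed extraction, PPI, group GLM and permutation inference."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from posbias.design import EventSchedule, build_event_schedule
from posbias.glm import (
    ROI_ALPHA,
    StatMap,
    build_design,
    build_ppi_design,
    extract_seed_timecourse,
    fit_first_level,
    gamma_hrf,
    group_glm,
    make_group_design,
    permutation_maxT,
    roi_small_volume,
    session_change,
    task_regressors,
)
from posbias.synthetic import BoldSimSpec, simulate_bold, simulate_motion


def _group_frame(n, rng):
    return pd.DataFrame({
        "hamd_improvement": rng.normal(9, 5, n),
        "hamd_baseline": rng.normal(18, 2.5, n),
        "age": rng.normal(39, 10, n),
        "gender_female": (rng.random(n) < 0.8).astype(float),
        "medication": (rng.random(n) < 0.6).astype(float),
        "n_itbs_sessions": rng.choice([7, 8, 9, 10], n).astype(float),
    })


class TestHrf:
    def test_kernel_sums_to_one(self):
        k = gamma_hrf(0.1)
        assert k.sum() == pytest.approx(1.0, abs=1e-12)
        assert (k >= 0).all()

    def test_peak_at_gamma_mode(self):
        dt, lag, disp = 0.01, 6.0, 3.0
        k = gamma_hrf(dt, lag, disp)
        shape = (lag / disp) ** 2
        scale = disp**2 / lag
        mode = (shape - 1) * scale
        assert np.argmax(k) * dt == pytest.approx(mode, abs=2 * dt)

    def test_refinement_consistency(self):
        k1 = gamma_hrf(0.2)
        k2 = gamma_hrf(0.1)
        np.testing.assert_allclose(k1, 2 * k2[::2], atol=1e-6)

    def test_invalid_parameters_rejected(self):
        for bad in ((0, 6, 3), (0.1, -1, 3), (0.1, 6, 0)):
            with pytest.raises(ValueError):
                gamma_hrf(*bad)


class TestDesign:
    def test_default_design_has_eleven_columns(self):
        sched = build_event_schedule()
        motion = simulate_motion(sched.n_volumes, 0)
        design = build_design(sched, motion)
        assert design.shape == (sched.n_volumes, 11)
        assert list(design.columns[:4]) == [
            "happy", "fearful", "happy_derivative", "fearful_derivative"]
        assert design.columns[-1] == "intercept"

    def test_empty_schedule_gives_zero_task_columns(self):
        sched = build_event_schedule()
        empty = EventSchedule(
            events=sched.events.iloc[0:0], tr=sched.tr, n_volumes=sched.n_volumes)
        design = build_design(empty, simulate_motion(sched.n_volumes, 0))
        assert (design.happy == 0).all() and (design.fearful == 0).all()

    def test_onset_shift_by_one_tr_shifts_regressor(self):
        sched = build_event_schedule()
        shifted_events = sched.events.copy()
        shifted_events["onset"] += sched.tr
        shifted = EventSchedule(events=shifted_events, tr=sched.tr,
                                n_volumes=sched.n_volumes + 1)
        xh0, _ = task_regressors(sched)
        xh1, _ = task_regressors(shifted)
        np.testing.assert_allclose(xh1[1:len(xh0)], xh0[:-1], atol=1e-10)

    def test_motion_length_mismatch_rejected(self):
        sched = build_event_schedule()
        with pytest.raises(ValueError, match="motion"):
            build_design(sched, np.zeros((10, 6)))


class TestFirstLevel:
    def test_noiseless_betas_recovered_to_1e8(self):
        spec = BoldSimSpec(noise_sd=0.0, beta_happy=1.3, beta_fear=0.6,
                           ppi_gain=1.0)
        run = simulate_bold(spec, 0)
        design = build_design(run.events, run.motion)
        maps = fit_first_level(run.data, design)
        act = spec.active_mask
        assert np.abs(maps["happy_gt_fixation"]["beta"].data[act] - 1.3).max() < 1e-8
        assert np.abs(maps["fearful_gt_fixation"]["beta"].data[act] - 0.6).max() < 1e-8
        assert np.abs(maps["happy_gt_fearful"]["beta"].data[act] - 0.7).max() < 1e-8

    def test_equal_betas_give_zero_contrast(self):
        spec = BoldSimSpec(noise_sd=0.0, beta_happy=0.9, beta_fear=0.9,
                           ppi_gain=1.0)
        run = simulate_bold(spec, 1)
        maps = fit_first_level(run.data, build_design(run.events, run.motion))
        act = spec.active_mask
        assert np.abs(maps["happy_gt_fearful"]["beta"].data[act]).max() < 1e-8

    def test_pure_noise_t_values_follow_student_t(self):
        spec = BoldSimSpec(noise_sd=1.0, beta_happy=0.0, beta_fear=0.0,
                           ppi_gain=1.0, latent_sd=0.0)
        tvals = []
        for s in range(4):
            run = simulate_bold(spec, 10 + s)
            maps = fit_first_level(run.data, build_design(run.events, run.motion))
            tvals.append(maps["happy_gt_fearful"]["t"].data.ravel())
        tvals = np.concatenate(tvals)
        df = spec.n_volumes - 11
        _, p = stats.kstest(tvals, "t", args=(df,))
        assert p > 0.01

    def test_length_mismatch_rejected(self):
        spec = BoldSimSpec()
        run = simulate_bold(spec, 0)
        design = build_design(run.events, run.motion).iloc[:-5]
        with pytest.raises(ValueError, match="match"):
            fit_first_level(run.data, design)

    def test_negative_bold_sign_helper_tags_and_negates(self):
        m = StatMap(np.ones((2, 2, 2)), name="c", kind="beta")
        flipped = m.as_negative_bold_change()
        assert (flipped.data == -1).all()
        assert flipped.sign == "deactivation_increase_positive"


class TestSessionChange:
    def test_identical_sessions_zero(self):
        m = StatMap(np.random.default_rng(0).normal(size=(4, 4, 4)), "c", "beta")
        assert np.abs(session_change(m, m).data).max() == 0.0

    def test_planted_delta_recovered(self):
        rng = np.random.default_rng(1)
        base = StatMap(rng.normal(size=(4, 4, 4)), "c", "beta")
        week2 = StatMap(base.data.copy(), "c", "beta")
        week2.data[2, 2, 2] += 0.7
        diff = session_change(week2, base)
        assert diff.data[2, 2, 2] == pytest.approx(0.7)
        assert np.abs(np.delete(diff.data.ravel(), 42)).max() == 0.0

    def test_antisymmetric_under_swap(self):
        rng = np.random.default_rng(2)
        a = StatMap(rng.normal(size=(3, 3, 3)), "c", "beta")
        b = StatMap(rng.normal(size=(3, 3, 3)), "c", "beta")
        np.testing.assert_array_equal(session_change(a, b).data,
                                      -session_change(b, a).data)

    def test_grid_mismatch_rejected(self):
        a = StatMap(np.zeros((3, 3, 3)), "c", "beta")
        b = StatMap(np.zeros((4, 4, 4)), "c", "beta")
        with pytest.raises(ValueError):
            session_change(a, b)


class TestSeedExtraction:
    def test_single_voxel_mask(self):
        bold = np.random.default_rng(0).normal(size=(3, 3, 3, 20))
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 2, 0] = True
        np.testing.assert_array_equal(extract_seed_timecourse(bold, mask),
                                      bold[1, 2, 0])

    def test_two_voxel_mean_and_loop_oracle(self):
        rng = np.random.default_rng(1)
        bold = rng.normal(size=(4, 4, 4, 15))
        mask = rng.random((4, 4, 4)) < 0.3
        mask[0, 0, 0] = True
        series = extract_seed_timecourse(bold, mask)
        brute = np.zeros(15)
        count = 0
        for i in range(4):
            for j in range(4):
                for k in range(4):
                    if mask[i, j, k]:
                        brute += bold[i, j, k]
                        count += 1
        np.testing.assert_allclose(series, brute / count, atol=1e-12)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            extract_seed_timecourse(np.zeros((2, 2, 2, 5)), np.zeros((2, 2, 2), bool))


class TestPpi:
    def test_zero_seed_gives_zero_interactions(self):
        sched = build_event_schedule()
        design = build_design(sched, simulate_motion(sched.n_volumes, 0))
        pdes = build_ppi_design(design, np.zeros(sched.n_volumes))
        assert (pdes.ppi_happy == 0).all() and (pdes.ppi_fearful == 0).all()

    def test_happy_coupled_target_yields_positive_ppi_contrast(self):
        spec = BoldSimSpec(noise_sd=0.3, ppi_gain=2.5, latent_sd=1.0)
        hits = 0
        for s in range(20):
            run = simulate_bold(spec, 200 + s)
            design = build_design(run.events, run.motion)
            seed_tc = extract_seed_timecourse(run.data, spec.seed_mask)
            maps = fit_first_level(run.data, build_ppi_design(design, seed_tc),
                                   contrasts=("happy_gt_fearful",))
            est = maps["ppi_happy_gt_fearful"]["beta"].data[spec.target_mask].mean()
            hits += est > 0
        assert hits >= 19

    def test_uncoupled_seed_ppi_t_calibrated(self):
        """With no condition-specific coupling the PPI t-values at non-seed
        voxels stay near a null distribution (loose check on tails)."""
        spec = BoldSimSpec(noise_sd=1.0, ppi_gain=1.0, beta_happy=0.5,
                           beta_fear=0.5, latent_sd=1.0)
        tvals = []
        for s in range(3):
            run = simulate_bold(spec, 300 + s)
            design = build_design(run.events, run.motion)
            seed_tc = extract_seed_timecourse(run.data, spec.seed_mask)
            maps = fit_first_level(run.data, build_ppi_design(design, seed_tc),
                                   contrasts=("happy_gt_fearful",))
            outside = ~(spec.seed_mask | spec.target_mask)
            tvals.append(maps["ppi_happy_gt_fearful"]["t"].data[outside])
        tvals = np.concatenate(tvals)
        assert np.mean(np.abs(tvals) > 2.0) < 0.10

    def test_seed_length_mismatch_rejected(self):
        sched = build_event_schedule()
        design = build_design(sched, simulate_motion(sched.n_volumes, 0))
        with pytest.raises(ValueError, match="length"):
            build_ppi_design(design, np.zeros(10))


class TestGroupLevel:
    def test_group_design_demeaned(self):
        gd = make_group_design(_group_frame(30, np.random.default_rng(0)))
        for col in gd.columns[:-1]:
            assert abs(gd[col].mean()) < 1e-10

    def test_planted_voxel_slope_recovered(self):
        rng = np.random.default_rng(3)
        n = 40
        fr = _group_frame(n, rng)
        maps = rng.normal(size=(n, 5, 5, 5))
        maps[:, 2, 2, 2] += 0.6 * fr.hamd_improvement.to_numpy()
        tmap = group_glm(list(maps), make_group_design(fr))
        peak = np.unravel_index(np.argmax(np.abs(tmap.data)), tmap.data.shape)
        assert peak == (2, 2, 2)

    def test_constant_maps_give_zero_t(self):
        fr = _group_frame(20, np.random.default_rng(4))
        maps = [np.full((3, 3, 3), 1.7)] * 20
        tmap = group_glm(maps, make_group_design(fr))
        assert np.abs(tmap.data).max() == 0.0

    def test_too_few_participants_rejected(self):
        fr = _group_frame(6, np.random.default_rng(5))
        with pytest.raises(ValueError, match="regressors"):
            group_glm([np.zeros((2, 2, 2))] * 6, make_group_design(fr))


class TestPermutation:
    def test_strong_effect_reaches_minimum_possible_p(self):
        rng = np.random.default_rng(6)
        n = 30
        fr = _group_frame(n, rng)
        maps = rng.normal(size=(n, 6, 6, 6))
        maps[:, 3, 3, 3] += 1.0 * fr.hamd_improvement.to_numpy()
        res = permutation_maxT(list(maps), make_group_design(fr), n_perm=200,
                               seed=0)
        assert res["p_fwe"].data[3, 3, 3] == pytest.approx(1 / 201)

    def test_identical_seed_identical_maps(self):
        rng = np.random.default_rng(7)
        maps = rng.normal(size=(20, 4, 4, 4))
        gd = make_group_design(_group_frame(20, rng))
        r1 = permutation_maxT(list(maps), gd, n_perm=150, seed=9)
        r2 = permutation_maxT(list(maps), gd, n_perm=150, seed=9)
        np.testing.assert_array_equal(r1["p_fwe"].data, r2["p_fwe"].data)

    def test_corrected_p_dominates_parametric_p_at_peak(self):
        rng = np.random.default_rng(8)
        maps = rng.normal(size=(25, 4, 4, 4))
        gd = make_group_design(_group_frame(25, rng))
        res = permutation_maxT(list(maps), gd, n_perm=300, seed=1)
        t = res["t"].data
        p_fwe = res["p_fwe"].data
        p_unc = 2 * stats.t.sf(np.abs(t), 25 - 7)
        assert (p_fwe >= p_unc - 1e-9).all()

    def test_too_few_permutations_rejected(self):
        rng = np.random.default_rng(9)
        maps = rng.normal(size=(20, 3, 3, 3))
        gd = make_group_design(_group_frame(20, rng))
        with pytest.raises(ValueError, match="n_perm"):
            permutation_maxT(list(maps), gd, n_perm=50, seed=0)


class TestRoi:
    def test_effect_planted_inside_single_roi(self):
        rng = np.random.default_rng(10)
        n = 35
        fr = _group_frame(n, rng)
        maps = rng.normal(size=(n, 6, 6, 6))
        maps[:, 1, 1, 1] += 0.9 * fr.hamd_improvement.to_numpy()
        masks = {}
        for i in range(6):
            m = np.zeros((6, 6, 6), bool)
            m[i, :2, :2] = True
            masks[f"roi{i}"] = m
        masks["roi1"][1, 1, 1] = True
        tab = roi_small_volume(list(maps), make_group_design(fr), masks,
                               n_perm=300, seed=2)
        tab = tab.set_index("roi")
        assert bool(tab.loc["roi1", "significant"])
        assert not tab.drop("roi1").significant.any()
        assert np.allclose(tab.alpha, 0.05 / 6)

    def test_empty_mask_rejected(self):
        rng = np.random.default_rng(11)
        maps = rng.normal(size=(20, 4, 4, 4))
        gd = make_group_design(_group_frame(20, rng))
        with pytest.raises(ValueError, match="no voxels"):
            roi_small_volume(list(maps), gd,
                             {"empty": np.zeros((4, 4, 4), bool)}, n_perm=100)

    def test_alpha_constant_is_bonferroni_over_six(self):
        assert ROI_ALPHA == pytest.approx(0.05 / 6)
        assert ROI_ALPHA == pytest.approx(0.0083, abs=5e-5)
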