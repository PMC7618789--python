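"""Group statistics: split-plot ANOVA (cross-checked against pingouin and
frozen R aov values), logistic/linear regressions (cross-checked against
statsmodels), Bonferroni, Cohen's d and baseline-table tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from posbias.fert import METRICS
from posbias.inference import (
    COVARIATES,
    InsufficientDataError,
    analysis_frame_from_cohort,
    baseline_table,
    bonferroni,
    cohens_d,
    emotion_followup_anova,
    linear_predict_improvement,
    logistic_predict_response,
    mixed_anova_time_by_response,
    per_emotion_session_values,
    split_plot_anova,
)


@pytest.fixture(scope="module")
def frame(small_cohort):
    return analysis_frame_from_cohort(small_cohort)


class TestSplitPlotAnova:
    def test_matches_pingouin_mixed_anova(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        n1, n2 = 9, 6
        y = rng.normal(size=(n1 + n2, 1, 2))
        groups = np.array(["a"] * n1 + ["b"] * n2)
        tab = split_plot_anova(y, groups, within_names=("time",))
        rows = [(s, groups[s], f"t{j}", y[s, 0, j])
                for s in range(n1 + n2) for j in range(2)]
        df = pd.DataFrame(rows, columns=["subject", "group", "time", "value"])
        ref = pg.mixed_anova(df, dv="value", within="time", subject="subject",
                             between="group")
        mine = {"response": tab[tab.effect == "response"].F.iloc[0],
                "time": tab[tab.effect == "time"].F.iloc[0],
                "time*response": tab[tab.effect == "time*response"].F.iloc[0]}
        theirs = dict(zip(("group", "time", "Interaction"), ref.F))
        assert mine["response"] == pytest.approx(theirs["group"], rel=1e-10)
        assert mine["time"] == pytest.approx(theirs["time"], rel=1e-10)
        assert mine["time*response"] == pytest.approx(theirs["Interaction"], rel=1e-10)

    def test_three_way_matches_r_aov_frozen_values(self):
        """Frozen oracle: R `aov` with Error(subject/(emotion*time)) on the
        dataset regenerated below (R 4.3.3, seed-matched construction)."""
        rng = np.random.default_rng(42)
        n1, n2, a, b = 7, 5, 6, 2
        y = rng.normal(size=(n1 + n2, a, b)) + rng.normal(size=(n1 + n2, 1, 1)) * 0.8
        groups = np.array(["r"] * n1 + ["n"] * n2)
        tab = split_plot_anova(y, groups, within_names=("emotion", "time"))
        f = dict(zip(tab.effect, tab.F))
        expected = {
            "response": 0.3042954023, "emotion": 1.1142825125,
            "emotion*response": 1.6069221004, "time": 0.0877011555,
            "time*response": 0.0012243124, "emotion*time": 0.7817530798,
            "emotion*time*response": 0.0569921353,
        }
        for effect, val in expected.items():
            assert f[effect] == pytest.approx(val, rel=1e-6)

    def test_interaction_equals_squared_t_of_deltas(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=(25, 1, 2))
        groups = np.array(["a"] * 14 + ["b"] * 11)
        tab = split_plot_anova(y, groups, within_names=("time",))
        deltas = y[:, 0, 1] - y[:, 0, 0]
        t, p = stats.ttest_ind(deltas[groups == "a"], deltas[groups == "b"])
        inter = tab[tab.effect == "time*response"].iloc[0]
        assert inter.F == pytest.approx(t**2, rel=1e-12)
        assert inter.p == pytest.approx(p, rel=1e-12)

    def test_identical_group_delta_means_give_exactly_zero_interaction(self):
        # same multiset of change scores in both groups -> interaction SS = 0
        y = np.zeros((12, 1, 2))
        y[:, 0, 1] = np.tile([-1.0, 0.0, 1.0], 4) + 1.0
        groups = np.array(["a"] * 6 + ["b"] * 6)
        tab = split_plot_anova(y, groups, within_names=("time",))
        inter = tab[tab.effect == "time*response"].iloc[0]
        assert inter.F == pytest.approx(0.0, abs=1e-10)
        assert inter.p == pytest.approx(1.0, abs=1e-6)

    def test_single_participant_class_rejected(self):
        y = np.zeros((5, 1, 2))
        groups = np.array(["a"] * 4 + ["b"])
        with pytest.raises(InsufficientDataError):
            split_plot_anova(y, groups)


class TestMetricAnova:
    def test_reports_interaction_and_table(self, frame):
        res = mixed_anova_time_by_response(frame, "pb_misclass")
        assert res.stat_name == "F"
        assert res.df == (1.0, float(res.n - 2))
        tab = res.extras["anova_table"]
        assert set(tab.effect) == {"response", "time", "time*response"}

    def test_emotion_followup_runs_and_degrades_gracefully(self, small_cohort, frame):
        values = per_emotion_session_values(small_cohort, metric="misclass")
        res = emotion_followup_anova(values, frame)
        assert res.df[0] == 5.0
        assert 0.0 <= res.p <= 1.0

    def test_all_zero_deltas_give_zero_interaction_f(self, frame):
        flat = frame.copy()
        flat["pb_ubh_week2"] = flat["pb_ubh_baseline"]
        res = mixed_anova_time_by_response(flat, "pb_ubh")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)


class TestLogistic:
    def test_matches_statsmodels_wald(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(11)
        n = 300
        fr = pd.DataFrame({
            "pb_misclass_delta": rng.normal(size=n),
            "hamd_baseline": rng.normal(18, 3, n), "age": rng.normal(40, 10, n),
            "gender_female": rng.integers(0, 2, n).astype(float),
            "medication": rng.integers(0, 2, n).astype(float),
            "n_itbs_sessions": rng.choice([7, 8, 9, 10], n).astype(float),
        })
        eta = 0.8 * fr.pb_misclass_delta - 0.05 * (fr.age - 40)
        fr["response"] = np.where(rng.random(n) < 1 / (1 + np.exp(-eta)),
                                  "responder", "non-responder")
        res = logistic_predict_response(fr, "pb_misclass")
        cols = ["pb_misclass_delta", *COVARIATES]
        X = sm.add_constant(fr[cols].astype(float))
        ref = sm.Logit((fr.response == "responder").astype(float), X).fit(disp=0)
        assert res.extras["method"] == "ml"
        assert res.extras["beta"] == pytest.approx(ref.params["pb_misclass_delta"],
                                                   rel=1e-6)
        assert res.statistic == pytest.approx(ref.tvalues["pb_misclass_delta"],
                                              rel=1e-5)

    def test_odds_ratio_is_exp_beta(self, frame):
        res = logistic_predict_response(frame, "pb_misclass")
        assert res.effect == pytest.approx(np.exp(res.extras["beta"]), rel=1e-12)

    def test_separation_falls_back_to_firth(self, frame):
        sep = frame.copy()
        sep["pb_ubh_delta"] = np.where(sep.response == "responder", 1.0, -1.0)
        res = logistic_predict_response(sep, "pb_ubh")
        assert res.extras["method"] == "firth"
        assert np.isfinite(res.extras["beta"])

    def test_confounded_signal_attenuated_by_adjustment(self):
        rng = np.random.default_rng(9)
        n = 400
        conf = rng.normal(size=n)
        resp = rng.random(n) < 1 / (1 + np.exp(-1.5 * conf))
        fr = pd.DataFrame({
            "pb_misclass_delta": conf + rng.normal(0, 0.5, n),
            "hamd_baseline": conf * 2 + 18,  # carries the true signal
            "age": rng.normal(40, 10, n), "gender_female": rng.integers(0, 2, n),
            "medication": rng.integers(0, 2, n),
            "n_itbs_sessions": rng.choice([7, 8, 9, 10], n),
            "response": np.where(resp, "responder", "non-responder"),
        })
        adj = logistic_predict_response(fr, "pb_misclass")
        unadj = logistic_predict_response(fr, "pb_misclass", covariates=())
        assert abs(adj.extras["beta"]) < abs(unadj.extras["beta"])


class TestLinear:
    def test_self_prediction_is_identity(self, frame):
        res = linear_predict_improvement(frame, "hamd_improvement", covariates=())
        assert res.effect == pytest.approx(1.0, abs=1e-10)
        assert res.extras["r_squared"] == pytest.approx(1.0, abs=1e-10)

    def test_planted_slope_recovered_within_ci(self):
        rng = np.random.default_rng(4)
        n, slope = 300, 2.5
        x = rng.normal(size=n)
        fr = pd.DataFrame({
            "x": x, "hamd_improvement": slope * x + rng.normal(0, 1, n),
            "hamd_baseline": rng.normal(18, 3, n), "age": rng.normal(40, 10, n),
            "gender_female": rng.integers(0, 2, n),
            "medication": rng.integers(0, 2, n),
            "n_itbs_sessions": rng.choice([7, 8, 9, 10], n),
        })
        res = linear_predict_improvement(fr, "x")
        se = abs(res.effect / res.statistic)
        assert abs(res.effect - slope) < 2.5 * se

    def test_rank_deficiency_names_collinear_column(self, frame):
        fr = frame.copy()
        fr["dup"] = fr["age"]
        with pytest.raises(ValueError, match="age|dup"):
            linear_predict_improvement(fr, "dup")


class TestUtilities:
    def test_bonferroni_printed_example(self):
        assert bonferroni([0.009], m=4)[0] == pytest.approx(0.036)

    def test_bonferroni_caps_and_preserves_order(self):
        p = np.array([0.4, 0.001, 0.0, 0.02])
        out = bonferroni(p, m=4)
        assert out[0] == 1.0 and out[2] == 0.0
        assert (np.argsort(out[[1, 3]]) == np.argsort(p[[1, 3]])).all()
        assert (out >= p).all()

    def test_bonferroni_rejects_invalid_p(self):
        with pytest.raises(ValueError):
            bonferroni([1.2])

    def test_cohens_d_zero_for_equal_means(self):
        x = [1.0, 2.0, 3.0]
        y = [3.0, 2.0, 1.0]
        assert cohens_d(x, y).effect == pytest.approx(0.0, abs=1e-12)

    def test_cohens_d_large_sample_limit(self):
        rng = np.random.default_rng(0)
        x = rng.normal(1.0, 1.0, 20000)
        y = rng.normal(0.0, 1.0, 20000)
        res = cohens_d(x, y)
        assert res.effect == pytest.approx(1.0, abs=0.05)
        lo, hi = res.effect_ci
        assert lo < res.effect < hi
        assert hi - lo < 0.1

    def test_cohens_d_ci_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        x, y = rng.normal(0.9, 1, 33), rng.normal(0, 1, 16)
        res = cohens_d(x, y)
        ref = pg.compute_effsize(x, y, eftype="cohen")
        assert res.effect == pytest.approx(ref, rel=1e-10)

    def test_zero_pooled_sd_flagged(self):
        with pytest.raises(ValueError, match="pooled SD"):
            cohens_d([1.0, 1.0], [1.0, 1.0])


class TestBaselineTable:
    def test_identical_groups_fisher_p_one(self):
        fr = pd.DataFrame({
            "response": ["responder"] * 8 + ["non-responder"] * 8,
            "age": list(range(8)) * 2,
            "hamd_baseline": [18.0] * 16,
            "gender_female": [1, 1, 1, 0] * 4,
            "medication": [1, 0] * 8,
        })
        tab = baseline_table(fr)
        fisher = tab[tab.test == "fisher_exact"]
        assert (fisher.p == 1.0).all()

    def test_fisher_matches_hypergeometric_enumeration(self):
        """2x2 gender table (28,13 / 5,3): Fisher p equals exhaustive
        enumeration of tables at fixed margins."""
        a, b, c, d = 28, 13, 5, 3
        n = a + b + c + d
        row1, col1 = a + b, a + c
        observed = stats.hypergeom.pmf(a, n, row1, col1)
        p_enum = sum(
            stats.hypergeom.pmf(k, n, row1, col1)
            for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1)
            if stats.hypergeom.pmf(k, n, row1, col1) <= observed * (1 + 1e-12)
        )
        _, p_scipy = stats.fisher_exact([[a, b], [c, d]])
        assert p_scipy == pytest.approx(p_enum, rel=1e-9)
        assert p_enum > 0.99  # the trial's gender split is non-significant

    def test_welch_t_on_unequal_variances(self):
        rng = np.random.default_rng(1)
        fr = pd.DataFrame({
            "response": ["responder"] * 40 + ["non-responder"] * 40,
            "age": np.concatenate([rng.normal(40, 2, 40), rng.normal(40, 15, 40)]),
            "hamd_baseline": rng.normal(18, 3, 80),
            "gender_female": rng.integers(0, 2, 80),
            "medication": rng.integers(0, 2, 80),
        })
        tab = baseline_table(fr).set_index("variable")
        x = fr[fr.response == "responder"].age
        y = fr[fr.response == "non-responder"].age
        t_ref, p_ref = stats.ttest_ind(x, y, equal_var=False)
        assert tab.loc["age", "statistic"] == pytest.approx(t_ref)
        assert tab.loc["age", "p"] == pytest.approx(p_ref)
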