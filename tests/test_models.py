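from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from lpexplore.cohort import AgentPolicy, simulate_cohort, _analyse_cohort
from lpexplore.glmm import MixedLogitResults
from lpexplore.models import (
    ChoiceModel,
    LeaveStayModel,
    compare_models,
    compute_vif,
    fit_performance_slopes,
    marginal_effects,
    zscore,
)


# ---------------------------------------------------------------------------
# performance slopes
# ---------------------------------------------------------------------------

class TestPerformanceSlopes:
    def _cohort_frame(self, slopes, n_trials=30, noise=0.05, seed=6):
        rng = np.random.default_rng(seed)
        rows = []
        for i, s in enumerate(slopes):
            for t in range(1, n_trials + 1):
                rows.append({
                    "participant_id": f"c{i:02d}",
                    "pe": 0.3 + s * t + rng.normal(0, noise),
                    "within_character_trial": t,
                })
        return pd.DataFrame(rows)

    def test_bimodal_cohort_recovered(self):
        # half the children learn (slope -0.01), half do not (slope 0)
        slopes = [-0.01] * 20 + [0.0] * 20
        res = fit_performance_slopes(self._cohort_frame(slopes))
        sc = res.scores.set_index("participant_id")["slope"]
        learners = sc[[f"c{i:02d}" for i in range(20)]]
        non_learners = sc[[f"c{i:02d}" for i in range(20, 40)]]
        assert abs(learners.mean() - (-0.01)) < 0.001
        assert abs(non_learners.mean() - 0.0) < 0.001
        # the two recovered clusters separate cleanly at the midpoint
        assert (learners < -0.005).sum() >= 18
        assert (non_learners > -0.005).sum() >= 18

    def test_identical_children_have_no_slope_variance(self):
        res = fit_performance_slopes(self._cohort_frame([-0.005] * 10, noise=0.0))
        assert res.random_slope_sd < 1e-4

    def test_improving_child_gets_negative_slope(self):
        # PE halves over the run -> performance score below zero
        df = self._cohort_frame([-0.008], noise=0.01)
        res = fit_performance_slopes(df)
        assert res.scores["slope"].iloc[0] < 0

    def test_too_few_trials_rejected(self):
        df = pd.DataFrame({"participant_id": ["a"], "pe": [0.1],
                           "within_character_trial": [1]})
        with pytest.raises(ValueError):
            fit_performance_slopes(df)


# ---------------------------------------------------------------------------
# VIF
# ---------------------------------------------------------------------------

class TestVif:
    def test_orthogonal_predictors_give_unit_vif(self):
        x1 = np.tile([1.0, -1.0], 50)
        x2 = np.tile([1.0, 1.0, -1.0, -1.0], 25)
        vif = compute_vif(pd.DataFrame({"x1": x1, "x2": x2}))
        assert np.allclose(vif, 1.0, atol=1e-10)

    def test_closed_form_for_correlation_08(self):
        # exact empirical correlation 0.8 between two columns
        z1 = np.tile([1.0, -1.0], 50)
        z2 = np.tile([1.0, 1.0, -1.0, -1.0], 25)
        x = z1
        y = 0.8 * z1 + 0.6 * z2
        vif = compute_vif(pd.DataFrame({"x": x, "y": y}))
        assert np.allclose(vif, 1.0 / (1.0 - 0.64), atol=1e-10)

    def test_duplicated_column_is_an_error_not_a_number(self):
        x = np.random.default_rng(0).normal(size=50)
        with pytest.raises(ValueError, match="rank deficient"):
            compute_vif(pd.DataFrame({"a": x, "b": x}))

    def test_leave_stay_design_has_low_collinearity(self, analysed_cohort):
        est, _, _, perf, _ = analysed_cohort
        model = LeaveStayModel.from_estimates(est, perf)
        vif = model.vif()
        assert (vif < 5).all()


# ---------------------------------------------------------------------------
# leave-stay model and marginal effects
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def leave_stay_fit():
    policy = AgentPolicy(session_rule="fixed", fixed_n_trials=40)
    trials, truth = simulate_cohort(60, policy, seed=77)
    est, events, table, perf, ls, cm = _analyse_cohort(trials, truth, choice_seed=77)
    return est, perf, ls, cm, table, truth


class TestLeaveStayModel:
    def test_interaction_recovery_at_scale(self):
        # generating performance x novelty coefficient 0.7: mean estimate over
        # replicates at 100 children within 0.1
        policy = AgentPolicy(session_rule="fixed", fixed_n_trials=40)
        policy = AgentPolicy(
            session_rule="fixed", fixed_n_trials=40,
            leave_coef={**policy.leave_coef, "performance:novelty": 0.7},
        )
        ests = []
        for r in range(8):
            trials, truth = simulate_cohort(100, policy, seed=900 + r)
            _, _, _, _, ls, _ = _analyse_cohort(trials, truth, choice_seed=r)
            frame = ls.to_frame().set_index("term")
            ests.append(frame.loc["performance:novelty", "beta"])
        assert abs(np.mean(ests) - 0.7) < 0.1

    def test_missing_lp_rows_are_counted(self, analysed_cohort):
        est, _, _, perf, _ = analysed_cohort
        model = LeaveStayModel.from_estimates(est, perf)
        n_first_char_trials = int(est.groupby(
            ["participant_id", "character_id"]).size().shape[0])
        assert model.dropped["missing_lp"] <= n_first_char_trials
        assert model.dropped["censored_final_trials"] == est["participant_id"].nunique()


class TestMarginalEffects:
    def test_zero_moderator_recovers_main_effect(self, leave_stay_fit):
        _, _, ls, _, _, _ = leave_stay_fit
        me = marginal_effects(ls, predictors=("novelty",), at=(0.0,))
        i = ls.exog_names.index("novelty")
        assert me["slope"].iloc[0] == pytest.approx(ls.params[i], abs=1e-12)

    def test_unit_moderator_adds_interaction(self, leave_stay_fit):
        _, _, ls, _, _, _ = leave_stay_fit
        me = marginal_effects(ls, predictors=("lp",), at=(1.0,))
        i = ls.exog_names.index("lp")
        j = ls.exog_names.index("performance:lp")
        assert me["slope"].iloc[0] == pytest.approx(ls.params[i] + ls.params[j], abs=1e-12)

    def test_delta_method_ci_matches_parametric_bootstrap(self, leave_stay_fit, rng):
        _, _, ls, _, _, _ = leave_stay_fit
        me = marginal_effects(ls, predictors=("novelty",), at=(1.0,))
        i = ls.exog_names.index("novelty")
        j = ls.exog_names.index("performance:novelty")
        idx = [i, j]
        draws = rng.multivariate_normal(ls.params[idx],
                                        ls.cov_params[np.ix_(idx, idx)], size=2000)
        boot = draws[:, 0] + draws[:, 1]
        boot_width = np.quantile(boot, 0.975) - np.quantile(boot, 0.025)
        delta_width = me["ci_high"].iloc[0] - me["ci_low"].iloc[0]
        assert abs(delta_width - boot_width) / boot_width < 0.05

    def test_absent_moderator_is_specification_error(self, leave_stay_fit):
        _, _, ls, _, _, _ = leave_stay_fit
        with pytest.raises(ValueError):
            marginal_effects(ls, predictors=("novelty",), moderator="age")


# ---------------------------------------------------------------------------
# choice model
# ---------------------------------------------------------------------------

class TestChoiceModel:
    def test_option_relabeling_symmetry(self, leave_stay_fit):
        _, _, _, _, table, _ = leave_stay_fit
        fit_a = ChoiceModel.from_choice_table(table, min_events=10).fit()
        flipped = table.copy()
        flipped["chose_option1"] = 1.0 - flipped["chose_option1"]
        for c in [c for c in flipped.columns if c.startswith("d_")]:
            flipped[c] = -flipped[c]
        fit_b = ChoiceModel.from_choice_table(flipped, min_events=10).fit()
        names = fit_a.exog_names
        for k, name in enumerate(names):
            if name == "intercept":
                assert fit_b.params[k] == pytest.approx(-fit_a.params[k], abs=1e-4)
            else:
                assert fit_b.params[k] == pytest.approx(fit_a.params[k], abs=1e-4)

    def test_softmax_agent_policy_recovery(self):
        # agent choosing by expected LP alone with known gain K: fitted
        # per-SD coefficient should match K rescaled to the sample SD, and
        # expected-PE should show no effect
        K = 0.9
        policy = AgentPolicy(
            session_rule="fixed", fixed_n_trials=40,
            choice_coef={"intercept": 0.0, "d_novelty": 0.0,
                         "d_expected_lp": K, "d_expected_pe": 0.0},
        )
        trials, truth = simulate_cohort(120, policy, seed=4242)
        _, _, table, _, _, cm = _analyse_cohort(trials, truth, choice_seed=4242)
        frame = cm.to_frame().set_index("term")
        emp_sd = table["d_expected_lp"].dropna().std(ddof=0)
        implied = K * emp_sd / policy.reference_scales["d_expected_lp"][1]
        row = frame.loc["d_expected_lp"]
        assert row["beta"] > 0
        assert abs(row["beta"] - implied) <= 2 * row["se"]
        pe_row = frame.loc["d_expected_pe"]
        assert pe_row["ci_low"] <= 0 <= pe_row["ci_high"]

    def test_too_few_events_rejected(self, leave_stay_fit):
        _, _, _, _, table, _ = leave_stay_fit
        with pytest.raises(ValueError, match="choice events"):
            ChoiceModel.from_choice_table(table.head(5), min_events=20)


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

def _fake_results(llf, k_fixed, nobs, endog):
    model = SimpleNamespace(n_groups=10, endog=endog, nobs=nobs,
                            exog_names=["x"] * k_fixed)
    return MixedLogitResults(model=model, params=np.zeros(k_fixed),
                             re_sd=0.1, cov_params=np.eye(k_fixed),
                             llf=llf, converged=True)


class TestModelComparison:
    def test_aic_arithmetic(self):
        y = np.zeros(500)
        res = _fake_results(llf=-350.0, k_fixed=6, nobs=500, endog=y)
        assert res.k_params == 7
        assert res.aic == pytest.approx(714.0)

    def test_identical_fits_tie(self, leave_stay_fit):
        _, _, _, cm, _, _ = leave_stay_fit
        comp = compare_models(cm, cm)
        assert comp["delta_aic"] == 0.0
        assert comp["delta_bic"] == 0.0

    def test_different_n_not_comparable(self):
        a = _fake_results(-350.0, 6, 500, np.zeros(500))
        b = _fake_results(-340.0, 6, 400, np.zeros(400))
        with pytest.raises(ValueError, match="different n"):
            compare_models(a, b)


class TestZscore:
    def test_constant_input_maps_to_zero(self):
        assert np.allclose(zscore([3.0, 3.0, 3.0]), 0.0)

    def test_population_standardisation(self):
        z = zscore([0.0, 5.0, 10.0])
        assert np.allclose(z, [-1.2247448, 0.0, 1.2247448], atol=1e-6)
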