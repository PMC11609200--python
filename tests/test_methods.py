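"""Estimators: OLS primitive vs normal equations, residual-invariance test
calibration, ICP/SR/IMP behavior on benchmark SCMs, scoring and voting."""

import numpy as np
import pandas as pd
import pytest

from envinvar import methods as M
from envinvar.logodds import apply_child_transform
from envinvar.scm import (
    Cohort,
    ROLE_PREDICTOR,
    ROLE_TARGET,
    build_scm,
    sample_multi_env,
    target_shift_preset,
)


def plain_cohort(df, target="Y", env=None):
    roles = {c: ROLE_PREDICTOR for c in df.columns}
    roles[target] = ROLE_TARGET
    if env is None:
        env = np.full(len(df), "e1", dtype=object)
    return Cohort(df, roles, np.asarray(env, dtype=object))


class TestEnumerate:
    def test_counts(self):
        assert len(M.enumerate_subsets(list("abc"))) == 7
        assert len(M.enumerate_subsets([f"v{i}" for i in range(7)])) == 127

    def test_singletons_only_with_cap(self):
        out = M.enumerate_subsets(list("abcd"), max_size=1)
        assert out == [("a",), ("b",), ("c",), ("d",)]

    def test_order_by_size_then_lexicographic(self):
        out = M.enumerate_subsets(list("ab"))
        assert out == [("a",), ("b",), ("a", "b")]

    def test_explosion_guard(self):
        with pytest.raises(ValueError):
            M.enumerate_subsets([f"v{i}" for i in range(20)])


class TestOLS:
    def test_zero_noise_exact_fit(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.standard_normal((50, 2)), columns=["a", "b"])
        df["Y"] = 3.0 + 2.0 * df["a"] - df["b"]
        fit = M.fit_ols(plain_cohort(df), "Y", ["a", "b"])
        assert np.max(np.abs(fit.residuals)) <= 1e-10

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20, 2))
        y = rng.standard_normal(20)
        df = pd.DataFrame(X, columns=["a", "b"])
        df["Y"] = y
        fit = M.fit_ols(plain_cohort(df), "Y", ["a", "b"])
        D = np.column_stack([np.ones(20), X])
        oracle = np.linalg.solve(D.T @ D, D.T @ y)
        assert np.allclose(fit.coef, oracle, atol=1e-8)

    def test_duplicated_column_raises_collinearity(self):
        df = pd.DataFrame({"a": np.arange(10.0)})
        df["b"] = df["a"]
        df["Y"] = np.random.default_rng(2).standard_normal(10)
        with pytest.raises(M.CollinearityError):
            M.fit_ols(plain_cohort(df), "Y", ["a", "b"])

    def test_full_model_training_mse_nests_subsets(self, recovery_train):
        preds = recovery_train.predictors
        full = M.fit_ols(recovery_train, "Y", preds)
        full_mse = np.mean(full.residuals**2)
        for subset in M.enumerate_subsets(preds, max_size=2):
            sub = M.fit_ols(recovery_train, "Y", list(subset))
            assert full_mse <= np.mean(sub.residuals**2) + 1e-12


class TestResidualInvariance:
    def test_type_one_error_controlled(self):
        rng = np.random.default_rng(7)
        alpha, reps = 0.05, 500
        rejections = 0
        env = np.repeat(["e1", "e2"], 100)
        for _ in range(reps):
            resid = rng.standard_normal(200)
            rejections += residual_p(resid, env) < alpha
        se = np.sqrt(alpha * (1 - alpha) / reps)
        assert rejections / reps <= alpha + 2 * se

    def test_shift_detected_with_high_power(self):
        rng = np.random.default_rng(8)
        resid = rng.standard_normal(400)
        env = np.repeat(["e1", "e2"], 200)
        resid[200:] += 5.0
        assert residual_p(resid, env) < 1e-3

    def test_variance_shift_detected(self):
        rng = np.random.default_rng(9)
        resid = rng.standard_normal(400)
        env = np.repeat(["e1", "e2"], 200)
        resid[200:] *= 4.0
        assert residual_p(resid, env) < 1e-3

    def test_identical_residuals_trivially_invariant(self):
        resid = np.zeros(40)
        env = np.repeat(["e1", "e2"], 20)
        assert residual_p(resid, env) == 1.0

    def test_single_environment_vacuous_with_warning(self):
        with pytest.warns(RuntimeWarning, match="single"):
            p = M.residual_invariance_test(np.arange(10.0), np.full(10, "e1"))
        assert p == 1.0


def residual_p(resid, env):
    return M.residual_invariance_test(resid, env)


class TestICP:
    def test_recovers_true_parents(self, recovery_scm):
        subsets = M.enumerate_subsets(["X1", "X2", "X3", "Z"])
        hits = 0
        reps = 40
        for r in range(reps):
            coh = sample_multi_env(recovery_scm, {"e1": 2000, "e2": 2000}, 100 + r)
            res = M.icp(coh, "Y", subsets)
            if res.final_predictor_set == ("X1", "X2"):
                hits += 1
        assert hits >= int(0.9 * reps)

    def test_final_set_contained_in_every_accepted_subset(self, recovery_train):
        subsets = M.enumerate_subsets(recovery_train.predictors)
        res = M.icp(recovery_train, "Y", subsets)
        if res.final_predictor_set:
            for m in res.accepted_models:
                assert set(res.final_predictor_set) <= set(m.subset)

    def test_na_when_no_subset_invariant(self, shift_scm):
        # the target's own mechanism shifts between training environments,
        # so no subset can have an invariant residual distribution
        coh = sample_multi_env(shift_scm, {"e1": 2000, "e2": 2000}, seed=4)
        res = M.icp(coh, "Y", M.enumerate_subsets(["X1", "X2", "X3"]))
        assert res.is_na
        scored = M.predict_and_score(res, coh, "Y")
        assert scored.test_mse is None

    def test_empty_intersection_falls_back_to_intercept(self):
        # two independent parents, environments that never separate them:
        # craft by feeding disjoint accepted subsets through a no-shift SCM
        rng = np.random.default_rng(12)
        n = 400
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        df = pd.DataFrame({"a": a, "b": b})
        df["Y"] = 5.0 + 0.0 * a + rng.standard_normal(n)
        env = np.repeat(["e1", "e2"], n // 2)
        coh = plain_cohort(df, env=env)
        res = M.icp(coh, "Y", [("a",), ("b",)])
        # Y depends on neither, both singletons invariant, intersection empty
        assert res.empty_intersection
        scored = M.predict_and_score(res, coh, "Y")
        assert scored.test_predictions is not None
        assert np.allclose(scored.test_predictions, df["Y"].mean())


class TestStableRegression:
    def test_picks_most_predictive_invariant_subset(self):
        # among all subsets of size <= 2, exactly {x1, x2} attains the best
        # prediction error; everything is invariant, so SR must pick it
        hits = 0
        reps = 40
        for r in range(reps):
            rng = np.random.default_rng(300 + r)
            n = 600
            x1 = rng.standard_normal(n)
            x2 = rng.standard_normal(n)
            noise_var = rng.standard_normal(n)
            y = 1.0 * x1 + 1.0 * x2 + 0.5 * rng.standard_normal(n)
            df = pd.DataFrame({"x1": x1, "x2": x2, "x3": noise_var, "Y": y})
            coh = plain_cohort(df, env=np.repeat(["e1", "e2"], n // 2))
            res = M.stable_regression(
                coh, "Y", M.enumerate_subsets(["x1", "x2", "x3"], max_size=2), seed=r
            )
            hits += res.final_predictor_set == ("x1", "x2")
        assert hits >= int(0.9 * reps)

    def test_exact_cv_tie_resolves_to_smaller_then_lexicographic(self):
        # constant target: every subset fits exactly, CV error ties at 0
        df = pd.DataFrame(
            {
                "b": np.random.default_rng(1).standard_normal(40),
                "a": np.random.default_rng(2).standard_normal(40),
            }
        )
        df["Y"] = 2.0
        coh = plain_cohort(df, env=np.repeat(["e1", "e2"], 20))
        res = M.stable_regression(
            coh, "Y", [("b", "a"), ("b",), ("a",)], seed=0
        )
        assert res.final_predictor_set == ("a",)

    def test_na_when_nothing_survives(self, shift_scm):
        coh = sample_multi_env(shift_scm, {"e1": 2000, "e2": 2000}, seed=5)
        res = M.stable_regression(coh, "Y", M.enumerate_subsets(["X1", "X2", "X3"]))
        assert res.is_na


@pytest.fixture(scope="module")
def imp_train():
    spec = target_shift_preset()
    scm = build_scm(spec)
    train = sample_multi_env(scm, {"e1": 3000, "e2": 3000}, seed=31)
    test = sample_multi_env(scm, {"test": 2000}, seed=131)
    ttr, tte, _ = apply_child_transform(
        train, test, "C", ["X1", "X2", "X3", "Y"], ["X1", "X2", "X3"]
    )
    return ttr, tte


class TestIMP:
    def test_accepts_models_under_matching_regime(self, imp_train):
        ttr, _ = imp_train
        res = M.imp_fit(ttr, "C", "Y", M.enumerate_subsets(["X1", "X2", "X3"]))
        assert res.accepted_models

    def test_single_candidate_with_open_thresholds_is_identity_average(
        self, imp_train
    ):
        ttr, tte = imp_train
        res = M.imp_fit(
            ttr, "C", "Y", [("X3",)], tau_inv=np.inf, c_pred=np.inf
        )
        assert len(res.accepted_models) == 1
        scored = M.predict_and_score(res, tte, "Y")
        m = res.accepted_models[0]
        eta = M._matching_scores(tte, "C", res.candidate_predictors)
        X2 = M._stage2_design(tte, m.subset, eta)
        direct = m.coef_pooled[0] + X2 @ m.coef_pooled[1:]
        assert np.allclose(scored.test_predictions, direct)

    def test_full_candidate_subset_is_structurally_rejected(self, imp_train):
        ttr, _ = imp_train
        res = M.imp_fit(ttr, "C", "Y", [("X1", "X2", "X3")])
        assert not res.accepted_models and res.is_na

    def test_beats_pooled_ols_under_target_intervention(self, imp_train):
        ttr, tte = imp_train
        subsets = M.enumerate_subsets(["X1", "X2", "X3"])
        imp = M.predict_and_score(M.imp_fit(ttr, "C", "Y", subsets), tte, "Y")
        ols = M.predict_and_score(
            M.ols_baseline(ttr, "Y", ["X1", "X2", "X3"]), tte, "Y"
        )
        assert imp.test_mse < ols.test_mse

    def test_imp_inv_acceptance_is_test_based(self, imp_train):
        ttr, _ = imp_train
        subsets = M.enumerate_subsets(["X1", "X2", "X3"])
        res = M.imp_inv_fit(ttr, "C", "Y", subsets)
        for m in res.accepted_models:
            assert m.invariance_pvalue is not None
            assert 0.0 <= m.invariance_pvalue <= 1.0

    def test_environment_relabeling_leaves_results_unchanged(self, imp_train):
        ttr, tte = imp_train
        subsets = M.enumerate_subsets(["X1", "X2", "X3"])
        base = M.predict_and_score(M.imp_fit(ttr, "C", "Y", subsets), tte, "Y")
        relabelled = ttr.copy()
        relabelled.env = np.where(ttr.env == "e1", "B", "A").astype(object)
        swapped = M.predict_and_score(
            M.imp_fit(relabelled, "C", "Y", subsets), tte, "Y"
        )
        assert {tuple(m.subset) for m in base.accepted_models} == {
            tuple(m.subset) for m in swapped.accepted_models
        }
        assert base.test_mse == pytest.approx(swapped.test_mse, abs=1e-10)


class TestScoring:
    def test_perfect_predictions_zero_mse(self, toy_cohort):
        res = M.MethodResult(
            M.OLS,
            [M.CandidateModel(("A",), accepted=True)],
            final_predictor_set=("A",),
            pooled_coef=np.array([0.0, 2.0]),
        )
        cohort = toy_cohort.copy()
        cohort.data["Y"] = 2.0 * cohort.data["A"]
        scored = M.predict_and_score(res, cohort, "Y")
        assert scored.test_mse == pytest.approx(0.0, abs=1e-20)

    def test_constant_mean_prediction_equals_population_variance(self, toy_cohort):
        y = toy_cohort.data["Y"].to_numpy()
        res = M.MethodResult(
            M.ICP,
            [M.CandidateModel(("A",), accepted=True)],
            final_predictor_set=(),
            pooled_coef=np.array([y.mean()]),
            empty_intersection=True,
        )
        scored = M.predict_and_score(res, toy_cohort, "Y")
        assert scored.test_mse == pytest.approx(np.mean((y - y.mean()) ** 2))


class TestVoting:
    @staticmethod
    def result_with(subsets):
        return M.MethodResult(
            M.IMP,
            [M.CandidateModel(tuple(s), accepted=True) for s in subsets],
        )

    def test_counts_membership(self):
        tally = M.vote_parents(
            [self.result_with([("A",), ("A", "B")])], variables=["A", "B", "C"]
        )
        assert tally.counts == {"A": 2, "B": 1, "C": 0}

    def test_empty_input_zero_tally(self):
        tally = M.vote_parents([self.result_with([])], variables=["A"])
        assert tally.counts == {"A": 0} and tally.n_accepted == 0

    def test_vote_conservation(self):
        subsets = [("A",), ("A", "B"), ("B", "C"), ("A", "B", "C")]
        tally = M.vote_parents([self.result_with(subsets)])
        assert tally.total_votes() == sum(len(s) for s in subsets)
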