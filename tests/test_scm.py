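"""Structural-causal-model generator: graph handling, sampling laws,
intervention semantics, determinism, and the cohort container."""

import numpy as np
import pytest
from scipy.special import expit

from envinvar.scm import (
    SCM,
    ChildSpec,
    Cohort,
    GraphError,
    InterventionSpec,
    SCMSpec,
    SpecError,
    build_scm,
    prism_preset,
    sample_environment,
    sample_multi_env,
    subseed,
    true_parents,
    PRISM_ACTIVE,
)


def tiny_spec(**overrides):
    base = dict(
        n_predictors=2,
        target_name="Y",
        target_parents={"X1": 1.0},
        noise_scales={"X1": 1.0, "X2": 1.0, "Y": 1.0},
    )
    base.update(overrides)
    return SCMSpec(**base)


class TestBuild:
    def test_no_edge_topological_order_lists_predictors_before_target(self):
        scm = build_scm(tiny_spec())
        order = scm.topo_order
        assert order.index("X1") < order.index("Y")
        assert set(order) == {"X1", "X2", "Y"}

    def test_cycle_raises_graph_error(self):
        with pytest.raises(GraphError):
            tiny_spec(edges=(("X1", "X2", 1.0), ("X2", "X1", 1.0)))

    def test_intervention_on_unknown_variable_rejected(self):
        with pytest.raises(SpecError, match="unknown"):
            tiny_spec(
                env_interventions={"e": (InterventionSpec("Q", "mean_shift", 1.0),)}
            )

    def test_intervention_on_child_mechanism_forbidden(self):
        child = ChildSpec("C", intercept=0.0, coef_target=1.0)
        with pytest.raises(SpecError, match="forbidden"):
            tiny_spec(
                children=(child,),
                env_interventions={"e": (InterventionSpec("C", "mean_shift", 1.0),)},
            )

    def test_child_requires_nonzero_target_coefficient(self):
        with pytest.raises(SpecError):
            ChildSpec("C", intercept=0.0, coef_target=0.0)

    def test_target_do_only_legal_on_target(self):
        with pytest.raises(SpecError):
            tiny_spec(
                env_interventions={"e": (InterventionSpec("X1", "target_do", 1.0),)}
            )


class TestSampling:
    def test_zero_noise_limit_target_is_exact_linear_combination(self):
        spec = tiny_spec(
            target_parents={"X1": 2.0, "X2": -1.0},
            noise_scales={"X1": 1.0, "X2": 1.0, "Y": 1e-12},
        )
        coh = sample_environment(build_scm(spec), "observational", 500, seed=3)
        y = coh.data["Y"].to_numpy()
        lin = 2.0 * coh.data["X1"].to_numpy() - coh.data["X2"].to_numpy()
        assert np.allclose(y, lin, atol=1e-9)

    def test_child_closed_form_prevalence(self):
        # intercept -2, no dependence: prevalence = expit(-2) = 0.119
        spec = tiny_spec(
            children=(
                ChildSpec("C", intercept=-2.0, coef_target=1e-12),
            ),
        )
        coh = sample_environment(build_scm(spec), "observational", 10_000, seed=4)
        p = expit(-2.0)
        se = np.sqrt(p * (1 - p) / 10_000)
        assert abs(coh.data["C"].mean() - p) < 3 * se

    def test_mean_shift_on_nonparent_leaves_target_residual_invariant(self):
        # module invariance: Y's law given its parents is unchanged when a
        # non-parent covariate is shifted
        spec = tiny_spec(
            env_interventions={"shifted": (InterventionSpec("X2", "mean_shift", 3.0),)}
        )
        scm = build_scm(spec)
        n = 5000
        resid_means = []
        for env in ("observational", "shifted"):
            coh = sample_environment(scm, env, n, seed=subseed(9, env))
            resid = coh.data["Y"] - 1.0 * coh.data["X1"]
            resid_means.append(resid.mean())
        se = np.sqrt(2.0 / n)  # Var(resid)=1 in both environments
        assert abs(resid_means[0] - resid_means[1]) < 3 * se

    def test_child_conditional_law_invariant_across_environments(self):
        # per-environment logistic fits of C on Y recover the child spec
        # within 4 SE even when the target itself is intervened on
        import statsmodels.api as sm

        child = ChildSpec("C", intercept=-0.5, coef_target=0.8)
        spec = tiny_spec(
            children=(child,),
            env_interventions={"do": (InterventionSpec("Y", "mean_shift", 2.0),)},
        )
        scm = build_scm(spec)
        for env in ("observational", "do"):
            coh = sample_environment(scm, env, 10_000, seed=subseed(21, env))
            res = sm.Logit(
                coh.data["C"], sm.add_constant(coh.data[["Y"]])
            ).fit(disp=0)
            assert abs(res.params.iloc[0] - child.intercept) < 4 * res.bse.iloc[0]
            assert abs(res.params.iloc[1] - child.coef_target) < 4 * res.bse.iloc[1]

    def test_target_do_overrides_parent_dependence(self):
        spec = tiny_spec(
            env_interventions={"do": (InterventionSpec("Y", "target_do", 5.0),)}
        )
        coh = sample_environment(build_scm(spec), "do", 4000, seed=8)
        y, x1 = coh.data["Y"].to_numpy(), coh.data["X1"].to_numpy()
        assert abs(y.mean() - 5.0) < 3 / np.sqrt(4000)
        assert abs(np.corrcoef(y, x1)[0, 1]) < 0.05

    def test_n_below_one_rejected(self):
        with pytest.raises(ValueError):
            sample_environment(build_scm(tiny_spec()), "observational", 0, seed=1)


class TestMultiEnv:
    def test_plan_counts(self):
        coh = sample_multi_env(build_scm(tiny_spec()), {"observational": 100}, seed=2)
        assert coh.n == 100
        spec = tiny_spec(env_interventions={"e2": ()})
        coh = sample_multi_env(build_scm(spec), {"observational": 100, "e2": 50}, 2)
        assert coh.n == 150
        assert int((coh.env == "e2").sum()) == 50

    def test_determinism_bit_identical(self):
        spec = tiny_spec(env_interventions={"e2": ()})
        scm = build_scm(spec)
        a = sample_multi_env(scm, {"observational": 50, "e2": 50}, seed=7)
        b = sample_multi_env(scm, {"observational": 50, "e2": 50}, seed=7)
        assert a.data.equals(b.data)

    def test_adding_environment_does_not_perturb_existing_draws(self):
        spec = tiny_spec(env_interventions={"e2": (), "e3": ()})
        scm = build_scm(spec)
        small = sample_multi_env(scm, {"observational": 50}, seed=7)
        big = sample_multi_env(scm, {"observational": 50, "e3": 20}, seed=7)
        assert np.array_equal(
            small.data.to_numpy(), big.data.to_numpy()[:50]
        )

    def test_empty_plan_rejected(self):
        with pytest.raises(ValueError):
            sample_multi_env(build_scm(tiny_spec()), {}, seed=1)


class TestPrismPreset:
    def test_seventeen_predictors_and_published_names(self):
        spec = prism_preset()
        assert spec.n_predictors == 17
        for name in PRISM_ACTIVE:
            assert name in spec.predictor_names
        scm = build_scm(spec)
        assert sum(1 for n in spec.predictor_names) == 17

    def test_prevalences_calibrated(self):
        coh = sample_environment(build_scm(prism_preset()), "observational", 2744, 5)
        for child, p in (("SI", 0.288), ("SB", 0.088)):
            se = np.sqrt(p * (1 - p) / 2744)
            assert abs(coh.data[child].mean() - p) < 3 * se

    def test_roles_cover_columns(self):
        coh = sample_environment(build_scm(prism_preset()), "observational", 50, 5)
        assert set(coh.roles) == set(coh.data.columns)
        assert len(coh.predictors) == 17
        assert coh.target == "SCS-R"
        assert set(coh.data["prior_SI"].unique()) <= {0.0, 1.0}


class TestOracle:
    def test_true_parents_of_target(self, recovery_scm):
        assert true_parents(recovery_scm, "Y") == {"X1", "X2"}

    def test_child_parents_include_target(self, recovery_scm):
        assert "Y" in true_parents(recovery_scm, "C")

    def test_isolated_predictor_has_no_parents(self, recovery_scm):
        assert true_parents(recovery_scm, "X2") == set()

    def test_unknown_variable_rejected(self, recovery_scm):
        with pytest.raises(ValueError):
            true_parents(recovery_scm, "nope")


class TestCohortContainer:
    def test_csv_roundtrip(self, toy_cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        toy_cohort.to_csv(path)
        back = Cohort.from_csv(path)
        assert back.roles == toy_cohort.roles
        assert np.array_equal(back.env, toy_cohort.env)
        assert np.allclose(back.data.to_numpy(), toy_cohort.data.to_numpy())

    def test_role_map_must_cover_every_column(self, toy_cohort):
        with pytest.raises(SpecError):
            Cohort(toy_cohort.data, {"A": "predictor"}, toy_cohort.env)

    def test_spec_yaml_roundtrip(self, tmp_path):
        spec = prism_preset()
        path = tmp_path / "spec.yaml"
        spec.to_yaml(path)
        back = SCMSpec.from_yaml(path)
        assert back == spec
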