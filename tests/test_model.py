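import numpy as np
import pytest
import statsmodels.api as sm

from shortcutaudit.cohort import DesignMatrix, encode_design_matrix
from shortcutaudit.model import (ConvergenceError, PowerSpec, QuasiSeparationError,
                                 RankDeficiencyError, fit_multinomial_logit,
                                 mcfadden_pseudo_r2, predict_probabilities,
                                 required_sample_size, vif, wald_tests)
from shortcutaudit.simulate import default_tcga_like_config, generate_cohort

from conftest import toy_model


def irls_binary_logistic(X, y, tol=1e-12, max_iter=200):
    """Independent binary-logistic oracle: textbook IRLS on the full design."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        W = p * (1 - p)
        z = eta + (y - p) / W
        beta_new = np.linalg.solve(X.T @ (X * W[:, None]), X.T @ (W * z))
        if np.max(np.abs(beta_new - beta)) < tol:
            return beta_new
        beta = beta_new
    raise RuntimeError("IRLS oracle did not converge")


@pytest.fixture
def toy20():
    """Fixed 20-row binary-response design (2 covariates + intercept)."""
    rng = np.random.default_rng(7)
    X = np.column_stack([np.ones(20), rng.normal(size=20),
                         rng.integers(0, 2, 20).astype(float)])
    eta = 0.5 + 1.2 * X[:, 1] - 0.8 * X[:, 2]
    y = (rng.random(20) < 1 / (1 + np.exp(-eta))).astype(int)
    return DesignMatrix(X, y, ["intercept", "x1", "b1"], ["neg", "pos"],
                        np.arange(20).astype(str))


class TestFit:
    def test_intercept_only_fit_recovers_log_proportion_ratios(self):
        y = np.array([0] * 50 + [1] * 30 + [2] * 20)
        design = DesignMatrix(np.ones((100, 1)), y, ["intercept"],
                              ["A", "B", "C"], np.arange(100).astype(str))
        model = fit_multinomial_logit(design)
        np.testing.assert_allclose(
            model.coefficients[:, 0], [np.log(30 / 50), np.log(20 / 50)],
            atol=1e-7)
        assert model.log_likelihood == pytest.approx(model.null_log_likelihood, abs=1e-8)

    def test_two_class_fit_matches_independent_irls_oracle(self, toy20):
        model = fit_multinomial_logit(toy20)
        oracle = irls_binary_logistic(toy20.X, (toy20.y == 1).astype(float))
        np.testing.assert_allclose(model.coefficients[0], oracle, atol=1e-6)

    def test_five_class_fit_matches_statsmodels_mnlogit(self, default_design):
        model = fit_multinomial_logit(default_design)
        sm_fit = sm.MNLogit(default_design.y, default_design.X).fit(
            method="newton", disp=0, maxiter=200, tol=1e-10)
        np.testing.assert_allclose(model.coefficients, sm_fit.params.T, atol=1e-5)
        assert model.log_likelihood == pytest.approx(sm_fit.llf, abs=1e-6)
        assert model.null_log_likelihood == pytest.approx(sm_fit.llnull, abs=1e-6)

    def test_parameter_recovery_within_three_se(self):
        cfg = default_tcga_like_config(n=5000, seed=0)
        design = encode_design_matrix(generate_cohort(cfg))
        model = fit_multinomial_logit(design)
        z = np.abs(model.coefficients - np.asarray(cfg.true_coefficients))
        z /= model.standard_errors().to_numpy()
        assert (z < 3).all()

    def test_log_likelihood_nondecreasing_along_iterations(self, default_fit):
        trace = np.asarray(default_fit.ll_trace)
        assert (np.diff(trace) >= -1e-9).all()
        assert default_fit.converged and default_fit.log_likelihood >= default_fit.null_log_likelihood

    def test_reference_relabeling_leaves_probabilities_invariant(self, default_cohort):
        d_a = encode_design_matrix(default_cohort, reference_class="LumA")
        d_b = encode_design_matrix(default_cohort, reference_class="Basal")
        p_a = predict_probabilities(fit_multinomial_logit(d_a), d_a)
        p_b = predict_probabilities(fit_multinomial_logit(d_b), d_b)
        for lab in d_a.class_labels:
            np.testing.assert_allclose(
                p_a[:, d_a.class_labels.index(lab)],
                p_b[:, d_b.class_labels.index(lab)], atol=1e-8)

    def test_rank_deficient_design_names_collinear_columns(self, toy20):
        X = np.column_stack([toy20.X, toy20.X[:, 2]])
        design = DesignMatrix(X, toy20.y, toy20.column_names + ["b1_copy"],
                              toy20.class_labels, toy20.patient_ids)
        with pytest.raises(RankDeficiencyError):
            fit_multinomial_logit(design)

    def test_separated_data_raises_quasi_separation_unless_ridge(self):
        # perfectly separating covariate
        x = np.concatenate([np.full(20, -1.0), np.full(20, 1.0)])
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(40), x + rng.normal(0, 1e-3, 40)])
        y = (x > 0).astype(int)
        design = DesignMatrix(X, y, ["intercept", "x"], ["a", "b"],
                              np.arange(40).astype(str))
        with pytest.raises((QuasiSeparationError, ConvergenceError)):
            fit_multinomial_logit(design)
        ridged = fit_multinomial_logit(design, ridge=0.1)
        assert ridged.converged


class TestPredict:
    def test_zero_coefficients_give_uniform_probabilities(self, tiny_design):
        model = toy_model(np.zeros((4, 3)), tiny_design.column_names,
                          ["A", "B", "C", "D", "E"])
        design5 = DesignMatrix(tiny_design.X, np.zeros(8, dtype=int),
                               tiny_design.column_names, ["A", "B", "C", "D", "E"],
                               tiny_design.patient_ids)
        np.testing.assert_allclose(predict_probabilities(model, design5), 0.2)

    def test_single_row_matches_hand_evaluated_softmax(self):
        B = np.array([[0.5, -1.0], [-0.2, 2.0]])
        model = toy_model(B, ["intercept", "x"], ["A", "B", "C"])
        design = DesignMatrix(np.array([[1.0, 3.0]]), np.array([0]),
                              ["intercept", "x"], ["A", "B", "C"], np.array(["p"]))
        eta = np.array([0.0, 0.5 - 3.0, -0.2 + 6.0])
        expected = np.exp(eta) / np.exp(eta).sum()
        np.testing.assert_allclose(predict_probabilities(model, design)[0],
                                   expected, atol=1e-12)

    def test_rows_sum_to_one(self, default_fit, default_design):
        probs = predict_probabilities(default_fit, default_design)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        assert (probs > 0).all() and (probs < 1).all()

    def test_column_mismatch_reports_both_sets(self, default_fit, tiny_design):
        with pytest.raises(ValueError, match="do not match"):
            predict_probabilities(default_fit, tiny_design)


class TestDiagnostics:
    def test_null_model_pseudo_r2_is_zero(self):
        y = np.array([0] * 5 + [1] * 4 + [2] * 3)
        design = DesignMatrix(np.ones((12, 1)), y, ["intercept"],
                              ["A", "B", "C"], np.arange(12).astype(str))
        assert mcfadden_pseudo_r2(fit_multinomial_logit(design)) == pytest.approx(0.0, abs=1e-9)

    def test_pseudo_r2_matches_direct_likelihood_recomputation(self, tiny_design):
        model = fit_multinomial_logit(tiny_design)
        probs = predict_probabilities(model, tiny_design)
        ll = np.log(probs[np.arange(8), tiny_design.y]).sum()
        counts = np.bincount(tiny_design.y)
        ll0 = (counts * np.log(counts / 8)).sum()
        assert mcfadden_pseudo_r2(model) == pytest.approx(1 - ll / ll0, abs=1e-8)

    def test_pseudo_r2_increases_with_truly_predictive_covariate(self, default_cohort):
        design = encode_design_matrix(default_cohort)
        j = design.column_names.index("pr_pos")
        reduced = DesignMatrix(np.delete(design.X, j, axis=1), design.y,
                               [c for c in design.column_names if c != "pr_pos"],
                               design.class_labels, design.patient_ids)
        assert (mcfadden_pseudo_r2(fit_multinomial_logit(design))
                > mcfadden_pseudo_r2(fit_multinomial_logit(reduced)))

    def test_orthogonal_design_vif_is_one(self):
        n = 64
        # mutually orthogonal +-1 contrasts
        a = np.tile([1.0, -1.0], n // 2)
        b = np.repeat([1.0, -1.0], 2)[None].repeat(n // 4, 0).ravel()
        X = np.column_stack([np.ones(n), a, b, a * b])
        design = DesignMatrix(X, np.zeros(n, int), ["intercept", "a", "b", "ab"],
                              ["x", "y"], np.arange(n).astype(str))
        np.testing.assert_allclose(vif(design)["vif"], 1.0, atol=1e-10)

    def test_correlated_pair_matches_closed_form(self):
        rng = np.random.default_rng(11)
        n = 20_000
        x1 = rng.normal(size=n)
        x2 = 0.8 * x1 + np.sqrt(1 - 0.64) * rng.normal(size=n)
        X = np.column_stack([np.ones(n), x1, x2])
        design = DesignMatrix(X, np.zeros(n, int), ["intercept", "x1", "x2"],
                              ["a", "b"], np.arange(n).astype(str))
        table = vif(design)
        assert table.loc["x1", "vif"] == pytest.approx(1 / (1 - 0.64), rel=0.05)

    def test_duplicated_column_yields_infinite_sentinel(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        X = np.column_stack([np.ones(50), x, x, rng.normal(size=50)])
        design = DesignMatrix(X, np.zeros(50, int),
                              ["intercept", "x", "x_copy", "z"], ["a", "b"],
                              np.arange(50).astype(str))
        table = vif(design)
        assert np.isinf(table.loc["x", "vif"]) and np.isinf(table.loc["x_copy", "vif"])
        assert np.isfinite(table.loc["z", "vif"])


class TestWald:
    def test_zero_coefficient_gives_z_zero_p_one(self):
        model = toy_model(np.zeros((1, 2)), ["intercept", "x"], ["A", "B"])
        table = wald_tests(model)
        assert (table["z"] == 0).all() and (table["p_value"] == 1).all()

    def test_z_of_1p96_gives_p_near_005(self):
        model = toy_model(np.array([[0.0, 1.96]]), ["intercept", "x"], ["A", "B"])
        table = wald_tests(model).set_index("column")
        assert table.loc["x", "p_value"] == pytest.approx(0.0500, abs=5e-4)

    def test_strong_pr_her2_truth_yields_significant_wald_tests(self, default_fit):
        table = wald_tests(default_fit).set_index(["class", "column"])
        assert table.loc[("Basal", "pr_pos"), "p_value"] < 0.01
        assert table.loc[("Her2E", "her2_pos"), "p_value"] < 0.01


class TestPower:
    @pytest.mark.parametrize("sides,expected", [(1, 99), (2, 126)])
    def test_one_sample_z_approximation(self, sides, expected):
        n, formula = required_sample_size(
            PowerSpec(effect_size_d=0.25, alpha=0.05, power=0.80, sides=sides))
        assert n == expected
        assert "ceil" in formula

    def test_zero_effect_size_is_an_error(self):
        with pytest.raises(ValueError):
            required_sample_size(PowerSpec(effect_size_d=0.0))


class TestSerialization:
    def test_json_round_trip_preserves_model_and_fingerprint(self, default_fit):
        from shortcutaudit.model import FittedSubtypeModel
        again = FittedSubtypeModel.from_json(default_fit.to_json())
        np.testing.assert_allclose(again.coefficients, default_fit.coefficients)
        assert again.class_labels == default_fit.class_labels
        assert again.fingerprint() == default_fit.fingerprint()
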