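import numpy as np
import pandas as pd
import pytest

from prsgxe.exceptions import (
    DegenerateDesignError,
    InsufficientDataError,
    InvalidInputError,
    SeparationError,
)
from prsgxe.formula import build_design, parse_formula
from prsgxe.regression import (
    FormulaRegressor,
    bonferroni_threshold,
    fit_linear,
    fit_logistic,
    residualize,
)


class TestFormulaGrammar:
    def test_parse_full_interaction_model(self):
        spec = parse_formula("bmi ~ 1 + prs + age + C(sex) + prs:C(activity)")
        assert spec.response == "bmi"
        assert spec.intercept
        assert len(spec.terms) == 4
        assert spec.variables == {"bmi", "prs", "age", "sex", "activity"}

    def test_no_intercept_categorical_full_coding(self):
        d = pd.DataFrame(
            {
                "y": [1.0, 2.0, 3.0, 4.0],
                "prs": [0.1, -0.2, 0.3, 0.5],
                "act": ["a", "b", "a", "b"],
            }
        )
        _, X = build_design(d, "y ~ 0 + prs + C(act) + C(act):I(prs > 0.0)")
        assert list(X.columns) == [
            "prs",
            "C(act)[a]",
            "C(act)[b]",
            "C(act)[a]:I(prs > 0)",
            "C(act)[b]:I(prs > 0)",
        ]

    def test_intercept_model_treatment_coding(self):
        d = pd.DataFrame({"y": [1.0, 2.0, 3.0], "sex": ["f", "m", "f"]})
        _, X = build_design(d, "y ~ 1 + C(sex)")
        assert list(X.columns) == ["Intercept", "C(sex)[T.m]"]

    def test_reference_level_override(self):
        d = pd.DataFrame({"y": [1.0, 2.0, 3.0], "sex": ["f", "m", "f"]})
        _, X = build_design(d, "y ~ 1 + C(sex)", references={"sex": "m"})
        assert list(X.columns) == ["Intercept", "C(sex)[T.f]"]

    def test_listwise_deletion(self):
        d = pd.DataFrame({"y": [1.0, np.nan, 3.0, 4.0], "x": [1.0, 2.0, np.nan, 4.0]})
        y, X = build_design(d, "y ~ 1 + x")
        assert len(y) == 2

    def test_unparseable_term_raises(self):
        with pytest.raises(InvalidInputError):
            parse_formula("y ~ 1 + log(x)")


class TestLinearFits:
    def test_exact_line_interpolation(self):
        d = pd.DataFrame({"x": np.arange(10.0)})
        d["y"] = 2.0 * d["x"] + 1.0
        fit = fit_linear("y ~ 1 + x", d, estimator="ols")
        assert fit.coefficients["Intercept"] == pytest.approx(1.0, abs=1e-10)
        assert fit.coefficients["x"] == pytest.approx(2.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert abs(fit.residuals.sum()) < 1e-8

    def test_constant_response(self):
        d = pd.DataFrame({"x": np.arange(8.0), "y": 3.0})
        fit = fit_linear("y ~ 1 + x", d, estimator="ols")
        assert fit.coefficients["x"] == pytest.approx(0.0, abs=1e-10)
        assert fit.r_squared == 0.0

    def test_ols_matches_normal_equations(self):
        rng = np.random.default_rng(1)
        d = pd.DataFrame(
            {"x1": rng.normal(size=40), "x2": rng.normal(size=40)}
        )
        d["y"] = 1.0 + 0.5 * d.x1 - 2.0 * d.x2 + rng.normal(size=40)
        fit = fit_linear("y ~ 1 + x1 + x2", d, estimator="ols")
        X = np.column_stack([np.ones(40), d.x1, d.x2])
        beta = np.linalg.solve(X.T @ X, X.T @ d.y.to_numpy())
        assert np.allclose(fit.coefficients.to_numpy(), beta, atol=1e-10)

    def test_r2_equals_squared_pearson_for_simple_regression(self):
        rng = np.random.default_rng(2)
        d = pd.DataFrame({"x": rng.normal(size=200)})
        d["y"] = 0.7 * d.x + rng.normal(size=200)
        fit = fit_linear("y ~ 1 + x", d, estimator="ols")
        r = np.corrcoef(d.x, d.y)[0, 1]
        assert fit.r_squared == pytest.approx(r**2, abs=1e-12)

    def test_robust_agrees_with_ols_on_clean_gaussian_data(self):
        rng = np.random.default_rng(3)
        d = pd.DataFrame({"x": rng.normal(size=2000)})
        d["y"] = 1.0 + 0.5 * d.x + rng.normal(size=2000)
        ols = fit_linear("y ~ 1 + x", d, estimator="ols")
        rob = fit_linear("y ~ 1 + x", d, estimator="robust")
        assert abs(ols.coefficients["x"] - rob.coefficients["x"]) < 0.01
        assert rob.converged
        assert rob.r_squared_is_diagnostic

    def test_robust_resists_gross_outliers(self):
        """With 5% +50 outliers the Huber slope beats OLS nearly always."""
        wins = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            n = 1000
            d = pd.DataFrame({"x": rng.normal(size=n)})
            d["y"] = 1.0 + 0.5 * d.x + rng.normal(size=n)
            idx = rng.choice(n, size=n // 20, replace=False)
            d.loc[idx, "y"] += 50.0
            ols = fit_linear("y ~ 1 + x", d, estimator="ols").coefficients["x"]
            rob = fit_linear("y ~ 1 + x", d, estimator="robust").coefficients["x"]
            wins += abs(rob - 0.5) < abs(ols - 0.5)
        assert wins >= 95

    def test_rank_deficiency_names_aliased_columns(self):
        d = pd.DataFrame({"y": np.arange(10.0), "x1": np.arange(10.0)})
        d["x2"] = d["x1"] * 2.0
        with pytest.raises(DegenerateDesignError) as exc:
            fit_linear("y ~ 1 + x1 + x2", d)
        assert exc.value.aliased

    def test_insufficient_cases(self):
        d = pd.DataFrame({"y": [1.0, 2.0, 3.0], "x": [1.0, 2.0, 3.0]})
        with pytest.raises(InsufficientDataError):
            fit_linear("y ~ 1 + x", d)


class TestLogistic:
    def test_two_by_two_closed_form_log_odds(self):
        # counts (a,b,c,d) = (30,10,10,30) -> slope log(9)
        d = pd.DataFrame(
            {
                "x": [1.0] * 40 + [0.0] * 40,
                "y": [1] * 30 + [0] * 10 + [1] * 10 + [0] * 30,
            }
        )
        fit = fit_logistic("y ~ 1 + x", d)
        assert fit.coefficients["x"] == pytest.approx(np.log(9.0), abs=1e-5)

    def test_balanced_null_table_zero_slope(self):
        d = pd.DataFrame(
            {"x": [1.0] * 40 + [0.0] * 40, "y": ([1] * 20 + [0] * 20) * 2}
        )
        fit = fit_logistic("y ~ 1 + x", d)
        assert fit.coefficients["x"] == pytest.approx(0.0, abs=1e-6)

    def test_independent_covariate_near_zero(self):
        rng = np.random.default_rng(4)
        d = pd.DataFrame({"x": rng.normal(size=3000)})
        d["y"] = (rng.random(3000) < 0.4).astype(int)
        fit = fit_logistic("y ~ 1 + x", d)
        assert abs(fit.coefficients["x"]) < 3 * fit.standard_errors["x"]

    def test_perfect_separation_raises(self):
        d = pd.DataFrame({"x": np.r_[np.ones(20), -np.ones(20)],
                          "y": [1] * 20 + [0] * 20})
        with pytest.raises(SeparationError):
            fit_logistic("y ~ 1 + x", d)

    def test_single_level_response_raises(self):
        d = pd.DataFrame({"x": np.arange(10.0), "y": 1})
        with pytest.raises(InvalidInputError):
            fit_logistic("y ~ 1 + x", d)


class TestResidualize:
    def test_intercept_only_centers_response(self):
        d = pd.DataFrame({"y": [1.0, 2.0, 6.0]})
        resid = residualize(d, "y", "1")
        assert np.allclose(resid, [-2.0, -1.0, 3.0])

    def test_orthogonality_to_covariates(self):
        rng = np.random.default_rng(6)
        d = pd.DataFrame(
            {
                "y": rng.normal(size=300),
                "age": rng.uniform(30, 60, 300),
                "sex": rng.choice(["f", "m"], 300),
            }
        )
        resid = residualize(d, "y", "1 + age + C(sex)")
        _, X = build_design(d.assign(r=resid), "r ~ 1 + age + C(sex)")
        inner = X.to_numpy().T @ resid.to_numpy()
        assert np.max(np.abs(inner)) / len(d) < 1e-8
        refit = fit_linear("r ~ 1 + age + C(sex)", d.assign(r=resid), estimator="ols")
        assert refit.r_squared == pytest.approx(0.0, abs=1e-12)


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,m,expected",
        [
            (0.05, 20, 2.5e-3),
            (0.05, 12, 0.05 / 12),
            (0.05, 1, 0.05),
        ],
    )
    def test_threshold_values(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expected, rel=1e-12)

    def test_invalid_family_size(self):
        with pytest.raises(InvalidInputError):
            bonferroni_threshold(0.05, 0)


class TestSklearnInterface:
    def test_get_set_params_and_fitted_attributes(self):
        rng = np.random.default_rng(7)
        d = pd.DataFrame({"x": rng.normal(size=50)})
        d["y"] = 2.0 + d.x + rng.normal(size=50) * 0.1
        reg = FormulaRegressor("y ~ 1 + x")
        assert reg.get_params()["estimator"] == "ols"
        reg.set_params(estimator="robust").fit(d)
        assert reg.n_used_ == 50
        assert reg.coefficients_["x"] == pytest.approx(1.0, abs=0.1)
        pred = reg.predict(d)
        assert np.corrcoef(pred, d.y)[0, 1] > 0.9
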