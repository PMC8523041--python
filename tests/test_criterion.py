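import numpy as np
import pandas as pd
import pytest
import scipy.linalg

from prsgxe.criterion import (
    CutoffSearch,
    compare_models,
    fit_criterion_model,
    search_cutoff,
    validate_replication,
)
from prsgxe.exceptions import (
    DegenerateDesignError,
    InsufficientDataError,
    InvalidInputError,
)
from prsgxe.regression import residualize


def brute_force_r2_profile(cohort, score="prs"):
    """Independent reimplementation of the cut-off grid search.

    Builds each per-percentile design matrix explicitly with pandas and
    solves the no-intercept OLS by QR factorization; R^2 is the uncentered
    1 - SSE / sum(y^2) of the fitted model.
    """
    d = cohort.loc[
        cohort[["bmi", "age", "sex", "physical_activity", score]].notna().all(axis=1)
    ]
    resid = residualize(d, "bmi", "1 + age + C(sex)")
    y = resid.to_numpy()
    frame = pd.DataFrame(
        {
            "prs": d[score].to_numpy(dtype=float),
            "active": (d["physical_activity"].astype(str) == "active").astype(float),
            "inactive": (d["physical_activity"].astype(str) == "inactive").astype(float),
        }
    )
    profile, skipped = {}, []
    for i in range(100):
        q = np.percentile(frame["prs"], i)
        above = frame["prs"] > q
        cells = pd.crosstab(above, frame["inactive"] == 1.0)
        if cells.shape != (2, 2) or (cells == 0).any().any():
            skipped.append(i)
            continue
        X = pd.DataFrame(
            {
                "prs": frame["prs"],
                "act_a": frame["active"],
                "act_i": frame["inactive"],
                "act_a_above": frame["active"] * above,
                "act_i_above": frame["inactive"] * above,
            }
        ).to_numpy()
        beta, _, _, _ = scipy.linalg.lstsq(X, y)
        sse = float(np.sum((y - X @ beta) ** 2))
        profile[i] = 1.0 - sse / float(y @ y)
    return profile, skipped


class TestSearchCutoff:
    def test_matches_bruteforce_oracle(self, threshold_cohort):
        cohort = threshold_cohort.iloc[:500]
        result = search_cutoff(cohort)
        oracle_profile, oracle_skipped = brute_force_r2_profile(cohort)
        assert sorted(result.r2_profile) == sorted(oracle_profile)
        assert [i for i, _ in result.skipped] == oracle_skipped
        for i, r2 in oracle_profile.items():
            assert result.r2_profile[i] == pytest.approx(r2, abs=1e-10)

    def test_recovers_generating_percentile(self, threshold_cohort):
        # generated with threshold_percentile=50, beta_threshold_int=2.0
        result = search_cutoff(threshold_cohort)
        assert abs(result.selected_percentile - 50) <= 5

    def test_selected_percentile_attains_max_and_ties_go_low(self, threshold_cohort):
        result = search_cutoff(threshold_cohort)
        best = max(result.r2_profile.values())
        assert result.r2_profile[result.selected_percentile] == best
        tied = [i for i, r2 in result.r2_profile.items() if r2 == best]
        assert result.selected_percentile == min(tied)

    def test_identical_indicators_tie_to_smallest_percentile(self):
        """Percentiles falling in the same score gap give identical designs,
        identical R^2, and the search must pick the smallest of them."""
        rng = np.random.default_rng(8)
        n = 50  # percentile spacing < 1 order statistic, so adjacent
        # percentiles interpolate inside the same inter-cluster gap
        prs = np.concatenate([rng.uniform(-2, -0.5, 25), rng.uniform(1.5, 2.5, 25)])
        prs = (prs - prs.mean()) / prs.std()
        inact = rng.random(n) < 0.4
        bmi = 25 + 1.0 * prs + 0.7 * inact + 2.5 * inact * (prs > 0) + rng.normal(0, 0.5, n)
        cohort = pd.DataFrame(
            {
                "bmi": bmi,
                "age": rng.uniform(30, 60, n),
                "sex": rng.choice(["female", "male"], n),
                "prs": prs,
                "physical_activity": pd.Categorical(
                    np.where(inact, "inactive", "active"),
                    categories=["active", "inactive"],
                ),
            }
        )
        result = search_cutoff(cohort, min_samples=40)
        best = max(result.r2_profile.values())
        tied = [i for i, r2 in result.r2_profile.items() if r2 == best]
        assert len(tied) > 1  # the gap produces genuinely tied cut-offs
        assert result.selected_percentile == min(tied)

    def test_empty_cell_skipped_with_reason(self):
        rng = np.random.default_rng(9)
        n = 300
        prs = np.sort(rng.standard_normal(n))
        prs = (prs - prs.mean()) / prs.std()
        inact = rng.random(n) < 0.4
        inact[-6:] = False  # nobody inactive above the 98th percentile
        cohort = pd.DataFrame(
            {
                "bmi": 25 + prs + 0.5 * inact + rng.normal(0, 1, n),
                "age": rng.uniform(30, 60, n),
                "sex": rng.choice(["female", "male"], n),
                "prs": prs,
                "physical_activity": pd.Categorical(
                    np.where(inact, "inactive", "active"),
                    categories=["active", "inactive"],
                ),
            }
        )
        result = search_cutoff(cohort)
        reasons = dict(result.skipped)
        assert reasons.get(99) == "empty activity x group cell"

    def test_insufficient_samples(self, threshold_cohort):
        with pytest.raises(InsufficientDataError):
            search_cutoff(threshold_cohort.iloc[:100])

    def test_estimator_predict_assigns_groups(self, threshold_cohort):
        est = CutoffSearch().fit(threshold_cohort)
        groups = est.predict(threshold_cohort)
        frac_high = (groups == "high").mean()
        assert frac_high == pytest.approx(1 - est.selected_percentile_ / 100, abs=0.02)


class TestCriterionModel:
    def test_hand_built_gaps_exact(self):
        # 2 samples per activity x group cell, integer BMI values
        cohort = pd.DataFrame(
            {
                "bmi": [24.0, 26.0, 25.0, 27.0, 24.0, 28.0, 28.0, 34.0],
                "age": [35.0, 40.0, 45.0, 50.0, 38.0, 42.0, 48.0, 52.0],
                "sex": ["female", "male"] * 4,
                "prs": [-1.5, -1.0, -0.5, -0.25, 0.5, 0.75, 1.0, 1.5],
                "physical_activity": pd.Categorical(
                    ["active", "active", "inactive", "inactive"] * 2,
                    categories=["active", "inactive"],
                ),
            }
        )
        ev = fit_criterion_model(cohort, 50, estimator="ols")
        # low group: inactive mean 26, active mean 25 -> gap 1
        # high group: inactive mean 31, active mean 26 -> gap 5
        assert ev.low_group_gap == pytest.approx(1.0)
        assert ev.high_group_gap == pytest.approx(5.0)
        assert ev.n_per_cell == {
            "low_active": 2,
            "low_inactive": 2,
            "high_active": 2,
            "high_inactive": 2,
        }

    def test_nested_r2_monotonicity(self, threshold_cohort):
        for cutoff in (25, 50, 78):
            ev = fit_criterion_model(threshold_cohort, cutoff)
            assert ev.r2_full >= ev.r2_no_interaction - 1e-12
            assert ev.delta_r2_threshold >= -1e-12

    def test_null_generator_gives_null_interaction(self, small_cohort):
        # small_cohort has a linear interaction but no threshold term; at a
        # mis-placed cut-off the extra threshold contrast stays moderate
        ev = fit_criterion_model(small_cohort, 50)
        assert ev.n_used == len(small_cohort)
        assert ev.delta_r2_threshold < 0.02

    def test_invalid_percentile(self, small_cohort):
        with pytest.raises(InvalidInputError):
            fit_criterion_model(small_cohort, 120)


class TestReplication:
    def test_identical_cohort_reproduces_discovery_evaluation(self, threshold_cohort):
        disc = fit_criterion_model(threshold_cohort, 50)
        rep = validate_replication(threshold_cohort, 50)
        assert rep.low_group_gap == pytest.approx(disc.low_group_gap)
        assert rep.high_group_gap == pytest.approx(disc.high_group_gap)
        assert rep.r2_full == pytest.approx(disc.r2_full)

    def test_all_active_cohort_rejected(self, threshold_cohort):
        cohort = threshold_cohort.copy()
        cohort["physical_activity"] = pd.Categorical(
            ["active"] * len(cohort), categories=["active", "inactive"]
        )
        with pytest.raises(DegenerateDesignError):
            validate_replication(cohort, 50)

    def test_three_level_labels_mapped(self):
        rng = np.random.default_rng(10)
        n = 600
        prs = rng.standard_normal(n)
        prs = (prs - prs.mean()) / prs.std()
        cohort = pd.DataFrame(
            {
                "bmi": 25 + prs + rng.normal(0, 2, n),
                "age": rng.uniform(20, 60, n),
                "sex": rng.choice(["female", "male"], n),
                "prs": prs,
                "activity_level": rng.choice(["sedentary", "moderate", "high"], n),
            }
        )
        ev = validate_replication(cohort, 50)
        assert ev.n_used == n


class TestCompareModels:
    def test_threshold_generator_prefers_threshold_model(self, threshold_cohort):
        out = compare_models(fit_criterion_model(threshold_cohort, 50))
        assert out["preferred"] == "threshold"
        assert out["delta_r2_threshold_pct"] > out["delta_r2_linear_pct"]

    def test_increments_reported_in_percentage_points(self, threshold_cohort):
        ev = fit_criterion_model(threshold_cohort, 50)
        out = compare_models(ev)
        assert out["delta_r2_threshold_pct"] == pytest.approx(
            100 * ev.delta_r2_threshold
        )
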