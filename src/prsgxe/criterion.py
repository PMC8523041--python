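"""Stage 3: percentile cut-off criterion for two-group risk stratification.

The criterion splits a cohort at a data-driven percentile of the
standardized polygenic score.  The cut-off is selected by a grid search:
BMI is residualized on ``1 + age + C(sex)`` (OLS) and, for each candidate
percentile i in 0..99, the no-intercept model

    BMI residuals ~ 0 + PRS + C(activity) + C(activity):I(PRS > q_i)

is fitted by OLS, where ``q_i`` is the i-th empirical percentile of the
observed scores and the indicator is strict ``>``.  The percentile with the
highest R-squared wins (ties resolved to the smallest percentile).  The
final criterion model and its nested comparators quantify what the
threshold interaction adds:

    full:    bmi ~ 1 + age + C(sex) + prs + C(activity) + C(activity):I(PRS > q)
    no-int:  bmi ~ 1 + age + C(sex) + prs + C(activity)
    linear:  bmi ~ 1 + age + C(sex) + prs + C(activity) + prs:C(activity)

Because the cut-off is optimized post hoc, its R-squared is upward-biased
under the null; validation therefore refits the criterion at the *fixed*
discovery percentile in an independent cohort, recomputing the percentile
value on that cohort's own score distribution (scores are standardized per
cohort, so the percentile — not the score value — transports).

Group-gap summaries are unadjusted mean BMI differences (inactive minus
active) within each score group; group membership uses the same strict
``>`` boundary as the search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .association import categorize_risk_factors
from .exceptions import (
    DegenerateDesignError,
    InsufficientDataError,
    InvalidInputError,
    SearchFailedError,
)
from .regression import fit_linear, residualize

_REQUIRED = ["bmi", "age", "sex", "physical_activity"]


@dataclass
class CutoffSearchResult:
    """R-squared profile and winner of the percentile grid search."""

    r2_profile: dict  # percentile -> R^2 (evaluated cut-offs only)
    selected_percentile: int
    selected_score_value: float
    skipped: list = field(default_factory=list)  # (percentile, reason)
    n_used: int = 0

    def to_dict(self) -> dict:
        return {
            "r2_profile": {int(k): float(v) for k, v in self.r2_profile.items()},
            "selected_percentile": int(self.selected_percentile),
            "selected_score_value": float(self.selected_score_value),
            "skipped": [[int(i), r] for i, r in self.skipped],
            "n_used": int(self.n_used),
        }


@dataclass
class CriterionEvaluation:
    """Criterion model fit at a fixed percentile, with nested comparators."""

    cutoff_percentile: int
    cutoff_value: float
    low_group_gap: float  # mean inactive - active BMI, scores at/below cut-off
    high_group_gap: float  # same, scores above the cut-off
    interaction_estimate: float
    interaction_p: float
    r2_full: float
    r2_no_interaction: float
    r2_linear_interaction: float
    delta_r2_threshold: float
    delta_r2_linear: float
    n_per_cell: dict
    n_used: int

    def to_dict(self) -> dict:
        out = {k: v for k, v in self.__dict__.items()}
        out["n_per_cell"] = {k: int(v) for k, v in self.n_per_cell.items()}
        return out


def _complete_cases(cohort: pd.DataFrame, score: str) -> pd.DataFrame:
    if "physical_activity" not in cohort.columns:
        cohort = categorize_risk_factors(cohort)
    missing = [c for c in _REQUIRED + [score] if c not in cohort.columns]
    if missing:
        raise InvalidInputError(f"cohort lacks columns: {missing}")
    d = cohort.loc[cohort[_REQUIRED + [score]].notna().all(axis=1)]
    levels = set(d["physical_activity"].astype(str).unique())
    if not {"active", "inactive"} <= levels:
        raise DegenerateDesignError(
            f"both activity levels required, observed: {sorted(levels)}"
        )
    return d


class CutoffSearch(BaseEstimator):
    """R-squared-maximizing percentile cut-off search (sklearn-style).

    Parameters
    ----------
    score:
        Column holding the standardized polygenic score.
    percentiles:
        Candidate percentiles; default ``range(100)``.
    min_samples:
        Minimum complete cases required to run the search.

    Fitted attributes: ``r2_profile_`` (dict percentile -> R^2),
    ``selected_percentile_``, ``selected_score_value_``, ``skipped_``,
    ``result_`` (a :class:`CutoffSearchResult`).
    """

    def __init__(self, score: str = "prs", percentiles=None, min_samples: int = 200):
        self.score = score
        self.percentiles = percentiles
        self.min_samples = min_samples

    def fit(self, cohort: pd.DataFrame, y=None) -> "CutoffSearch":
        d = _complete_cases(cohort, self.score)
        if len(d) < self.min_samples:
            raise InsufficientDataError(
                f"cut-off search needs >= {self.min_samples} complete cases, got {len(d)}"
            )
        resid = residualize(d, "bmi", "1 + age + C(sex)")
        prs = d[self.score].to_numpy(dtype=float)
        yv = resid.to_numpy()
        inactive = (d["physical_activity"].astype(str) == "inactive").to_numpy()
        act_a = (~inactive).astype(float)
        act_i = inactive.astype(float)
        base = np.column_stack([prs, act_a, act_i])
        yss = float(yv @ yv)

        candidates = list(self.percentiles) if self.percentiles is not None else list(range(100))
        profile: dict[int, float] = {}
        skipped: list[tuple[int, str]] = []
        for i in candidates:
            q = np.percentile(prs, i)
            ind = (prs > q).astype(float)
            cells = [
                (act_a * ind).sum(),
                (act_i * ind).sum(),
                (act_a * (1 - ind)).sum(),
                (act_i * (1 - ind)).sum(),
            ]
            if min(cells) == 0:
                skipped.append((i, "empty activity x group cell"))
                continue
            X = np.column_stack([base, act_a * ind, act_i * ind])
            beta, sse, rank, _ = np.linalg.lstsq(X, yv, rcond=None)
            if rank < X.shape[1]:
                skipped.append((i, "rank-deficient design"))
                continue
            sse = float(sse[0]) if sse.size else float(np.sum((yv - X @ beta) ** 2))
            profile[i] = 1.0 - sse / yss  # uncentered R^2 (no-intercept model)
        if not profile:
            raise SearchFailedError("every candidate cut-off was skipped")

        best_i, best_r2 = None, -np.inf
        for i in sorted(profile):
            if profile[i] > best_r2:
                best_i, best_r2 = i, profile[i]
        self.r2_profile_ = profile
        self.selected_percentile_ = int(best_i)
        self.selected_score_value_ = float(np.percentile(prs, best_i))
        self.skipped_ = skipped
        self.n_used_ = len(d)
        self.result_ = CutoffSearchResult(
            r2_profile=profile,
            selected_percentile=self.selected_percentile_,
            selected_score_value=self.selected_score_value_,
            skipped=skipped,
            n_used=len(d),
        )
        return self

    def predict(self, cohort: pd.DataFrame) -> pd.Series:
        """Assign "low"/"high" risk groups at the fitted percentile.

        The percentile is recomputed on the passed cohort's own score
        distribution (scores are standardized per cohort); the boundary is
        the search-time strict ``>``.
        """
        scores = (
            cohort[self.score] if isinstance(cohort, pd.DataFrame) else pd.Series(cohort)
        ).astype(float)
        q = np.percentile(scores.dropna().to_numpy(), self.selected_percentile_)
        return pd.Series(
            np.where(scores > q, "high", "low"), index=scores.index, name="risk_group"
        )


def search_cutoff(
    cohort: pd.DataFrame,
    score: str = "prs",
    percentiles=None,
    min_samples: int = 200,
) -> CutoffSearchResult:
    """Functional wrapper over :class:`CutoffSearch`."""
    return CutoffSearch(score=score, percentiles=percentiles, min_samples=min_samples).fit(
        cohort
    ).result_


def fit_criterion_model(
    cohort: pd.DataFrame,
    cutoff_percentile: int,
    score: str = "prs",
    estimator: str = "robust",
) -> CriterionEvaluation:
    """Fit the criterion model and nested comparators at a fixed percentile.

    R-squared values and their increments come from OLS fits on identical
    samples (so the threshold increment is non-negative by nesting); the
    interaction p-value uses ``estimator`` (robust by default, matching the
    main interaction scan).  Group gaps are raw mean BMI differences.
    """
    if not 0 <= int(cutoff_percentile) <= 99:
        raise InvalidInputError(f"cutoff_percentile must be in [0, 99], got {cutoff_percentile}")
    d = _complete_cases(cohort, score)
    prs = d[score].to_numpy(dtype=float)
    q = float(np.percentile(prs, cutoff_percentile))
    d = d.assign(high_prs=(prs > q).astype(float))
    inactive = d["physical_activity"].astype(str) == "inactive"
    high = d["high_prs"] == 1.0

    n_per_cell = {
        "low_active": int((~high & ~inactive).sum()),
        "low_inactive": int((~high & inactive).sum()),
        "high_active": int((high & ~inactive).sum()),
        "high_inactive": int((high & inactive).sum()),
    }
    if min(n_per_cell.values()) == 0:
        raise DegenerateDesignError(f"empty activity x group cell: {n_per_cell}")

    full_f = (
        f"bmi ~ 1 + age + C(sex) + {score} + C(physical_activity)"
        " + C(physical_activity):high_prs"
    )
    noint_f = f"bmi ~ 1 + age + C(sex) + {score} + C(physical_activity)"
    linear_f = noint_f + f" + {score}:C(physical_activity)"

    ols_full = fit_linear(full_f, d, estimator="ols")
    ols_noint = fit_linear(noint_f, d, estimator="ols")
    ols_linear = fit_linear(linear_f, d, estimator="ols")
    inference = ols_full if estimator == "ols" else fit_linear(full_f, d, estimator=estimator)
    int_col = "C(physical_activity)[T.inactive]:high_prs"

    gaps = {}
    for name, grp in (("low", ~high), ("high", high)):
        gaps[name] = float(
            d.loc[grp & inactive, "bmi"].mean() - d.loc[grp & ~inactive, "bmi"].mean()
        )

    return CriterionEvaluation(
        cutoff_percentile=int(cutoff_percentile),
        cutoff_value=q,
        low_group_gap=gaps["low"],
        high_group_gap=gaps["high"],
        interaction_estimate=float(inference.coefficients[int_col]),
        interaction_p=float(inference.p_values[int_col]),
        r2_full=float(ols_full.r_squared),
        r2_no_interaction=float(ols_noint.r_squared),
        r2_linear_interaction=float(ols_linear.r_squared),
        delta_r2_threshold=float(ols_full.r_squared - ols_noint.r_squared),
        delta_r2_linear=float(ols_linear.r_squared - ols_noint.r_squared),
        n_per_cell=n_per_cell,
        n_used=len(d),
    )


def validate_replication(
    replication_cohort: pd.DataFrame,
    cutoff_percentile: int,
    score: str = "prs",
    estimator: str = "robust",
) -> CriterionEvaluation:
    """Refit the criterion in an independent cohort at the fixed percentile.

    Three-level activity labels ("sedentary"/"moderate"/"high") are mapped
    to inactive/active during categorization; the cut-off percentile is
    transported from discovery and recomputed on the replication cohort's
    own score distribution.
    """
    if "physical_activity" not in replication_cohort.columns:
        replication_cohort = categorize_risk_factors(replication_cohort)
    return fit_criterion_model(
        replication_cohort, cutoff_percentile, score=score, estimator=estimator
    )


def compare_models(evaluation: CriterionEvaluation) -> dict:
    """R-squared increments (percentage points) of both interaction forms."""
    dt = 100.0 * evaluation.delta_r2_threshold
    dl = 100.0 * evaluation.delta_r2_linear
    return {
        "delta_r2_threshold_pct": dt,
        "delta_r2_linear_pct": dl,
        "preferred": "threshold" if dt >= dl else "linear",
    }
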