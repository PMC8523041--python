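"""Stage 2: score x risk-factor interaction scan and related checks.

The interaction model is ``bmi ~ 1 + score + age + C(sex) + C(factor) +
score:C(factor)``; each non-reference category contributes one interaction
contrast, and the scan applies a single family-wise Bonferroni threshold to
all contrasts (default family size 12 for the seven-factor set).

Also provided: the score-squared non-linearity test (residualize BMI on the
linear score plus covariates, then regress the residuals on the squared
score), and the activity-score dependence check (logistic regression of
activity status on age, sex and the score).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateScoreError, InvalidInputError
from .regression import FitResult, bonferroni_threshold, fit_linear, fit_logistic, residualize

DEFAULT_FAMILY_SIZE = 12


@dataclass
class InteractionResult:
    """Per-factor main effects and interaction contrasts from one model fit."""

    factor: str
    score: str
    main_effects: pd.DataFrame  # index: category; columns estimate/se/p_value
    interactions: pd.DataFrame  # index: category (non-reference only)
    n_used: int
    fit: FitResult


def test_interaction(
    cohort: pd.DataFrame,
    factor: str,
    score: str = "prs",
    estimator: str = "robust",
) -> InteractionResult:
    """Fit the score x factor interaction model and extract the contrasts."""
    if factor not in cohort.columns:
        raise InvalidInputError(f"factor column '{factor}' absent (categorize first?)")
    formula = f"bmi ~ 1 + {score} + age + C(sex) + C({factor}) + {score}:C({factor})"
    fit = fit_linear(formula, cohort, estimator=estimator)
    main_prefix = f"C({factor})[T."
    int_prefix = f"{score}:C({factor})[T."
    mains, ints = {}, {}
    for name in fit.coefficients.index:
        row = {
            "estimate": fit.coefficients[name],
            "se": fit.standard_errors[name],
            "p_value": fit.p_values[name],
        }
        if name.startswith(int_prefix):
            ints[name[len(int_prefix):-1]] = row
        elif name.startswith(main_prefix):
            mains[name[len(main_prefix):-1]] = row
    return InteractionResult(
        factor=factor,
        score=score,
        main_effects=pd.DataFrame.from_dict(mains, orient="index"),
        interactions=pd.DataFrame.from_dict(ints, orient="index"),
        n_used=fit.n_used,
        fit=fit,
    )


def interaction_scan(
    cohort: pd.DataFrame,
    factors: list[str] | None = None,
    score: str = "prs",
    estimator: str = "robust",
    alpha: float = 0.05,
    family_size: int | None = None,
) -> pd.DataFrame:
    """Interaction scan over several factors under one family-wise threshold.

    Returns one row per interaction contrast; the set of significant results
    is reproducible from the ``p_value`` column and ``attrs['threshold']``.
    """
    from .association import RISK_FACTORS

    factors = factors or [f for f in RISK_FACTORS if f in cohort.columns]
    rows, errors = [], []
    for factor in factors:
        try:
            res = test_interaction(cohort, factor, score=score, estimator=estimator)
        except Exception as exc:
            errors.append((factor, str(exc)))
            continue
        for category, row in res.interactions.iterrows():
            rows.append(
                {
                    "factor": factor,
                    "category": category,
                    "estimate": row["estimate"],
                    "se": row["se"],
                    "p_value": row["p_value"],
                    "n_used": res.n_used,
                }
            )
    if not rows:
        raise InvalidInputError(f"no interaction contrasts could be tested: {errors}")
    table = pd.DataFrame(rows)
    m = family_size or DEFAULT_FAMILY_SIZE
    threshold = bonferroni_threshold(alpha, m)
    table["significant"] = table["p_value"] < threshold
    table.attrs["family_size"] = m
    table.attrs["threshold"] = threshold
    table.attrs["errors"] = errors
    return table


def nonlinearity_test(cohort: pd.DataFrame, score: str = "prs") -> dict:
    """Quadratic-score check for non-linear genetic effects on BMI.

    Residualizes BMI on ``1 + score + age + C(sex)`` (OLS, keeping the
    orthogonality exact) and regresses the residuals on the squared
    standardized score.  Returns the quadratic coefficient and its p-value.
    """
    if score not in cohort.columns:
        raise InvalidInputError(f"score column '{score}' absent")
    used = cohort.loc[cohort[["bmi", score, "age", "sex"]].notna().all(axis=1)]
    if used[score].std(ddof=0) == 0:
        raise DegenerateScoreError(f"score '{score}' has zero variance")
    resid = residualize(used, "bmi", f"1 + {score} + age + C(sex)")
    stage2 = pd.DataFrame(
        {"resid": resid, "score_sq": used[score].loc[resid.index] ** 2}
    )
    fit = fit_linear("resid ~ 1 + score_sq", stage2, estimator="ols")
    return {
        "coefficient": float(fit.coefficients["score_sq"]),
        "p_value": float(fit.p_values["score_sq"]),
        "n_used": fit.n_used,
    }


def activity_dependence_test(cohort: pd.DataFrame, score: str = "prs") -> FitResult:
    """Logistic check that activity status is not driven by the score.

    Fits ``physical_activity ~ 1 + age + C(sex) + score`` with "active" as
    the reference level, so the reported coefficient is the log-odds of
    being *inactive* per standardized score unit.
    """
    if "physical_activity" not in cohort.columns:
        raise InvalidInputError("physical_activity column absent (categorize first?)")
    observed = cohort["physical_activity"].dropna().unique()
    if len(observed) < 2:
        raise InvalidInputError("physical activity has a single observed level")
    return fit_logistic(
        f"physical_activity ~ 1 + age + C(sex) + {score}",
        cohort,
        references={"physical_activity": "active"},
    )


def region_sensitivity_scan(
    cohort: pd.DataFrame,
    score_excluded: str,
    factor: str = "physical_activity",
    estimator: str = "robust",
) -> InteractionResult:
    """Interaction rerun with a region-excluded score column.

    ``score_excluded`` names a standardized score computed after dropping a
    locus window (e.g. the FTO region) from the weight table; the model is
    otherwise identical to :func:`test_interaction`.
    """
    if score_excluded not in cohort.columns:
        raise InvalidInputError(f"score column '{score_excluded}' absent")
    if abs(np.nanstd(cohort[score_excluded].to_numpy()) - 1.0) > 0.05:
        raise InvalidInputError("region-excluded score must be standardized")
    return test_interaction(cohort, factor, score=score_excluded, estimator=estimator)
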