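"""Stage 1: risk-factor categorization and association scans.

Derives the seven behavioral/environmental risk-factor categories from raw
questionnaire measures, tests score-trait and risk-factor-BMI associations
under a study-wise Bonferroni correction, and summarizes BMI by score decile
and by explained variance.

Category boundary rules (closed lists, fixed):

* physical activity — "inactive" at <= 225 min/week of commuting plus
  leisure-time activity, "active" strictly above;
* alcohol — "high" strictly above 6 units/week for women, 12 for men;
* diet — "healthy diet" at >= 9 DQS points, "poor diet" below;
* mental health — "high" strictly above the within-sex 75th percentile of
  the MCS score, computed on the analysis cohort itself;
* sleep — "poor" iff the insomnia answer is "yes";
* socioeconomic class — five-level composite of employment and education;
* smoking — four self-reported levels passed through unchanged.

Reference levels (first category of each ordered factor) follow the
association table convention: active, no-or-moderate alcohol, healthy diet,
high mental health, good sleep, working with >= 4 years of education,
never smoker.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import InvalidCategoryError, InvalidInputError
from .regression import bonferroni_threshold, fit_linear
from .synthetic import (
    ACTIVITY_THRESHOLD_MIN_WEEK,
    ALCOHOL_LIMIT,
    DQS_HEALTHY_MIN,
    SMOKING_CATEGORIES,
    SOCIOECONOMIC_CATEGORIES,
)

RISK_FACTORS = [
    "smoking",
    "alcohol",
    "diet",
    "physical_activity",
    "mental_health",
    "sleep",
    "socioeconomic",
]

FACTOR_CATEGORIES = {
    "smoking": SMOKING_CATEGORIES,
    "alcohol": ["no or moderate", "high"],
    "diet": ["healthy diet", "poor diet"],
    "physical_activity": ["active", "inactive"],
    "mental_health": ["high", "low"],
    "sleep": ["good", "poor"],
    "socioeconomic": SOCIOECONOMIC_CATEGORIES,
}

_GENOTEK_ACTIVITY_MAP = {"sedentary": "inactive", "moderate": "active", "high": "active"}


def _categorical(values, factor: str) -> pd.Categorical:
    return pd.Categorical(values, categories=FACTOR_CATEGORIES[factor])


def categorize_risk_factors(cohort: pd.DataFrame) -> pd.DataFrame:
    """Append the seven derived risk-factor category columns.

    Missing raw measures propagate to missing categories (logged per factor
    in ``attrs['categorization_log']``).  Unknown labels in closed-list raw
    columns raise :class:`InvalidCategoryError`.
    """
    out = cohort.copy()
    log: dict[str, int] = {}

    if "smoking_status" in out.columns:
        raw = out["smoking_status"]
        bad = set(raw.dropna().unique()) - set(SMOKING_CATEGORIES)
        if bad:
            raise InvalidCategoryError(f"unknown smoking labels: {sorted(bad)}")
        out["smoking"] = _categorical(raw, "smoking")
        log["smoking"] = int(raw.isna().sum())

    if "alcohol_units_week" in out.columns:
        units = out["alcohol_units_week"].astype(float)
        limit = out["sex"].astype(str).map(ALCOHOL_LIMIT)
        label = np.where(units > limit, "high", "no or moderate")
        out["alcohol"] = _categorical(
            np.where(units.notna() & limit.notna(), label, None), "alcohol"
        )
        log["alcohol"] = int(out["alcohol"].isna().sum())

    if "dqs" in out.columns:
        dqs = out["dqs"].astype(float)
        label = np.where(dqs >= DQS_HEALTHY_MIN, "healthy diet", "poor diet")
        out["diet"] = _categorical(np.where(dqs.notna(), label, None), "diet")
        log["diet"] = int(dqs.isna().sum())

    if "activity_min_week" in out.columns:
        minutes = out["activity_min_week"].astype(float)
        label = np.where(minutes > ACTIVITY_THRESHOLD_MIN_WEEK, "active", "inactive")
        out["physical_activity"] = _categorical(
            np.where(minutes.notna(), label, None), "physical_activity"
        )
        log["physical_activity"] = int(minutes.isna().sum())
    elif "activity_level" in out.columns:
        raw = out["activity_level"]
        bad = set(raw.dropna().unique()) - set(_GENOTEK_ACTIVITY_MAP)
        if bad:
            raise InvalidCategoryError(f"unknown activity labels: {sorted(bad)}")
        out["physical_activity"] = _categorical(
            raw.map(_GENOTEK_ACTIVITY_MAP), "physical_activity"
        )
        log["physical_activity"] = int(raw.isna().sum())

    if "mcs" in out.columns:
        mcs = out["mcs"].astype(float)
        label = pd.Series(index=out.index, dtype=object)
        for s in out["sex"].dropna().unique():
            sel = (out["sex"] == s) & mcs.notna()
            if sel.any():
                q75 = np.percentile(mcs[sel], 75)
                label[sel] = np.where(mcs[sel] > q75, "high", "low")
        out["mental_health"] = _categorical(label, "mental_health")
        log["mental_health"] = int(out["mental_health"].isna().sum())

    if "insomnia" in out.columns:
        raw = out["insomnia"]
        bad = set(raw.dropna().unique()) - {"yes", "no"}
        if bad:
            raise InvalidCategoryError(f"unknown insomnia labels: {sorted(bad)}")
        out["sleep"] = _categorical(
            raw.map({"no": "good", "yes": "poor"}), "sleep"
        )
        log["sleep"] = int(raw.isna().sum())

    if {"employment", "education"} <= set(out.columns):
        emp, edu = out["employment"], out["education"]
        bad = set(emp.dropna().unique()) - {"working", "not working"}
        if bad:
            raise InvalidCategoryError(f"unknown employment labels: {sorted(bad)}")
        label = pd.Series(index=out.index, dtype=object)
        both = emp.notna() & edu.notna()
        working = both & (emp == "working")
        label[working & (edu == "no education")] = "working, no education"
        label[working & (edu == "1-3 years")] = "working, 1-3 years of education"
        label[working & (edu == ">= 4 years")] = "working, >= 4 years of education"
        notw = both & (emp == "not working")
        label[notw & (edu == "no education")] = "not working, no education"
        label[notw & (edu != "no education")] = "not working, >= 1 year of education"
        out["socioeconomic"] = _categorical(label, "socioeconomic")
        log["socioeconomic"] = int(out["socioeconomic"].isna().sum())

    out.attrs["categorization_log"] = log
    return out


def _flag_significance(table: pd.DataFrame, family_size: int, alpha: float) -> pd.DataFrame:
    threshold = bonferroni_threshold(alpha, family_size)
    table = table.copy()
    table["significant"] = table["p_value"] < threshold
    table.attrs["family_size"] = family_size
    table.attrs["threshold"] = threshold
    return table


def run_trait_associations(
    cohort: pd.DataFrame,
    traits: list[str] | None = None,
    score: str = "prs",
    use_gpcs: bool = True,
    estimator: str = "robust",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Score-trait association scan: ``trait ~ 1 + score + age + C(sex) [+ gPCs]``.

    One fit per trait; per-trait fit errors are recorded in the table rather
    than aborting the batch.  Significance is family-wise Bonferroni at
    ``alpha / n_traits``.
    """
    if traits is None:
        traits = sorted(
            (c for c in cohort.columns if c.startswith("trait_")),
            key=lambda c: int(c.split("_")[1]),
        )
    if not traits:
        raise InvalidInputError("no traits to test")
    gpc_terms = ""
    if use_gpcs:
        gpcs = [c for c in ("gpc1", "gpc2", "gpc3") if c in cohort.columns]
        gpc_terms = "".join(f" + {g}" for g in gpcs)
    rows = []
    for trait in traits:
        formula = f"{trait} ~ 1 + {score} + age + C(sex){gpc_terms}"
        try:
            fit = fit_linear(formula, cohort, estimator=estimator)
            rows.append(
                {
                    "outcome": trait,
                    "term": score,
                    "estimate": fit.coefficients[score],
                    "se": fit.standard_errors[score],
                    "p_value": fit.p_values[score],
                    "n_used": fit.n_used,
                    "error": "",
                }
            )
        except Exception as exc:  # recorded, not fatal to the batch
            rows.append(
                {
                    "outcome": trait,
                    "term": score,
                    "estimate": np.nan,
                    "se": np.nan,
                    "p_value": np.nan,
                    "n_used": 0,
                    "error": str(exc),
                }
            )
    return _flag_significance(pd.DataFrame(rows), len(traits), alpha)


def run_risk_factor_associations(
    cohort: pd.DataFrame,
    factors: list[str] | None = None,
    score: str = "prs",
    estimator: str = "robust",
    alpha: float = 0.05,
    family_size: int | None = None,
) -> pd.DataFrame:
    """Risk-factor-BMI associations: ``bmi ~ 1 + score + age + C(sex) + C(factor)``.

    Reports one row per non-reference category contrast, relative to the
    declared reference group.  The Bonferroni family counts category
    contrasts (12 for the full seven-factor set), configurable via
    ``family_size``.
    """
    factors = factors or RISK_FACTORS
    rows, skipped = [], []
    for factor in factors:
        if factor not in cohort.columns:
            skipped.append((factor, "column absent"))
            continue
        observed = cohort[factor].dropna().unique()
        if len(observed) < 2:
            skipped.append((factor, "single observed level"))
            continue
        formula = f"bmi ~ 1 + {score} + age + C(sex) + C({factor})"
        fit = fit_linear(formula, cohort, estimator=estimator)
        prefix = f"C({factor})[T."
        for name in fit.coefficients.index:
            if name.startswith(prefix):
                rows.append(
                    {
                        "factor": factor,
                        "category": name[len(prefix):-1],
                        "estimate": fit.coefficients[name],
                        "se": fit.standard_errors[name],
                        "p_value": fit.p_values[name],
                        "n_used": fit.n_used,
                    }
                )
    if not rows:
        raise InvalidInputError("no risk-factor contrasts could be tested")
    table = pd.DataFrame(rows)
    table = _flag_significance(table, family_size or len(table), alpha)
    table.attrs["skipped"] = skipped
    return table


def decile_summary(cohort: pd.DataFrame, score: str = "prs") -> pd.DataFrame:
    """Per-decile BMI summary and the top-minus-bottom-decile median gap."""
    decile_col = f"{score}_decile"
    if decile_col not in cohort.columns:
        from .scoring import standardize_and_rank

        ranks = standardize_and_rank(cohort[score].to_numpy(), sample_ids=cohort.index)
        cohort = cohort.assign(**{decile_col: ranks["decile"].to_numpy()})
    d = cohort.loc[cohort["bmi"].notna() & cohort[decile_col].notna()]
    grouped = d.groupby(decile_col, observed=True)["bmi"]
    table = pd.DataFrame(
        {
            "n": grouped.size(),
            "median_bmi": grouped.median(),
            "q25_bmi": grouped.quantile(0.25),
            "q75_bmi": grouped.quantile(0.75),
        }
    ).reset_index(names="decile")
    top = table.loc[table["decile"] == table["decile"].max(), "median_bmi"].iloc[0]
    bottom = table.loc[table["decile"] == table["decile"].min(), "median_bmi"].iloc[0]
    table.attrs["top_bottom_median_diff"] = float(top - bottom)
    return table


def compare_explained_variance(
    cohort: pd.DataFrame, prs_col: str = "prs", grs_col: str = "grs"
) -> dict:
    """OLS R-squared of ``bmi ~ 1 + score`` for the PRS and GRS on shared samples."""
    d = cohort.loc[cohort[[prs_col, grs_col, "bmi"]].notna().all(axis=1)]
    prs_fit = fit_linear(f"bmi ~ 1 + {prs_col}", d, estimator="ols")
    grs_fit = fit_linear(f"bmi ~ 1 + {grs_col}", d, estimator="ols")
    return {
        "prs_r2": prs_fit.r_squared,
        "grs_r2": grs_fit.r_squared,
        "n_used": prs_fit.n_used,
    }
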