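"""Shared model-fitting engine.

Ordinary least squares, Huber M-estimation (robust) linear fits and logistic
fits over the formula grammar of :mod:`prsgxe.formula`.  Fitting is delegated
to statsmodels; this module owns design construction, input validation,
rank diagnostics and the uniform :class:`FitResult` container.

The robust fit uses iteratively reweighted least squares with the Huber
psi-function (tuning constant 1.345, i.e. 95% Gaussian efficiency) and a
median-absolute-deviation scale, re-estimated each iteration — the
conventional default of the statsmodels/R tool family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm
from sklearn.base import BaseEstimator
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .exceptions import (
    DegenerateDesignError,
    InsufficientDataError,
    InvalidInputError,
    SeparationError,
)
from .formula import ModelSpec, build_design, parse_formula

HUBER_T = 1.345
MAX_ITER = 50
TOL = 1e-8


@dataclass
class FitResult:
    """Summary of one fitted model."""

    coefficients: pd.Series
    standard_errors: pd.Series
    p_values: pd.Series
    r_squared: float | None
    residuals: pd.Series
    n_used: int
    converged: bool
    estimator: str
    formula: str = ""
    r_squared_is_diagnostic: bool = False
    extra: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.coefficients,
                "se": self.standard_errors,
                "p_value": self.p_values,
            }
        )


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy()
    if arr.shape[0] < arr.shape[1]:
        raise InsufficientDataError(
            f"{arr.shape[0]} complete cases for {arr.shape[1]} design columns"
        )
    _, r, piv = scipy.linalg.qr(arr, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(arr.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < arr.shape[1]:
        aliased = [X.columns[i] for i in piv[rank:]]
        raise DegenerateDesignError("rank-deficient design", aliased=aliased)


class FormulaRegressor(BaseEstimator):
    """Formula-driven linear/robust/logistic regressor (sklearn-style).

    Parameters
    ----------
    formula:
        Model formula, e.g. ``"bmi ~ 1 + prs + age + C(sex)"``.
    estimator:
        ``"ols"``, ``"robust"`` (Huber M-estimation) or ``"logistic"``.
    references:
        Optional mapping from categorical variable name to its reference
        level; defaults to the first (ordered) category.

    Fitted attributes (trailing underscore) mirror :class:`FitResult`,
    which is also exposed as ``result_``.
    """

    def __init__(
        self,
        formula: str,
        estimator: str = "ols",
        references: dict | None = None,
        huber_t: float = HUBER_T,
        max_iter: int = MAX_ITER,
        tol: float = TOL,
    ):
        self.formula = formula
        self.estimator = estimator
        self.references = references
        self.huber_t = huber_t
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, data: pd.DataFrame, y=None) -> "FormulaRegressor":
        if self.estimator not in {"ols", "robust", "logistic"}:
            raise InvalidInputError(f"unknown estimator {self.estimator!r}")
        spec = parse_formula(self.formula) if isinstance(self.formula, str) else self.formula
        y_raw, X = build_design(data, spec, self.references)
        _check_rank(X)
        if len(X) < X.shape[1] + 2:
            raise InsufficientDataError(
                f"need at least p+2={X.shape[1] + 2} complete cases, got {len(X)}"
            )
        if self.estimator == "logistic":
            result = self._fit_logistic(y_raw, X, spec)
        elif self.estimator == "robust":
            result = self._fit_robust(y_raw.astype(float), X, spec)
        else:
            result = self._fit_ols(y_raw.astype(float), X, spec)
        self.result_ = result
        self.coefficients_ = result.coefficients
        self.standard_errors_ = result.standard_errors
        self.p_values_ = result.p_values
        self.r_squared_ = result.r_squared
        self.residuals_ = result.residuals
        self.n_used_ = result.n_used
        self.converged_ = result.converged
        self.design_columns_ = list(X.columns)
        return self

    def predict(self, data: pd.DataFrame) -> pd.Series:
        spec = parse_formula(self.formula) if isinstance(self.formula, str) else self.formula
        _, X = build_design(data, spec, self.references)
        eta = X.to_numpy() @ self.coefficients_.reindex(X.columns).to_numpy()
        if self.estimator == "logistic":
            eta = 1.0 / (1.0 + np.exp(-eta))
        return pd.Series(eta, index=X.index, name=spec.response)

    # -- backends ---------------------------------------------------------

    def _fit_ols(self, y: pd.Series, X: pd.DataFrame, spec: ModelSpec) -> FitResult:
        res = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = float(res.rsquared)
        if not np.isfinite(r2):
            r2 = 0.0  # constant response: no variance to explain
        return FitResult(
            coefficients=pd.Series(res.params, index=X.columns),
            standard_errors=pd.Series(res.bse, index=X.columns),
            p_values=pd.Series(res.pvalues, index=X.columns),
            r_squared=r2,
            residuals=pd.Series(res.resid, index=X.index),
            n_used=len(X),
            converged=True,
            estimator="ols",
            formula=spec.formula,
        )

    def _fit_robust(self, y: pd.Series, X: pd.DataFrame, spec: ModelSpec) -> FitResult:
        model = sm.RLM(y.to_numpy(), X.to_numpy(), M=sm.robust.norms.HuberT(t=self.huber_t))
        res = model.fit(maxiter=self.max_iter, tol=self.tol, scale_est="mad", conv="coefs")
        n_iter = len(res.fit_history.get("params", []))
        # diagnostic weighted R^2 on the final IRLS solution
        w = res.weights
        resid = res.resid
        ybar = np.average(y.to_numpy(), weights=w)
        sst = float(np.sum(w * (y.to_numpy() - ybar) ** 2))
        sse = float(np.sum(w * resid**2))
        r2 = 1.0 - sse / sst if sst > 0 else np.nan
        return FitResult(
            coefficients=pd.Series(res.params, index=X.columns),
            standard_errors=pd.Series(res.bse, index=X.columns),
            p_values=pd.Series(res.pvalues, index=X.columns),
            r_squared=float(r2),
            residuals=pd.Series(resid, index=X.index),
            n_used=len(X),
            converged=n_iter < self.max_iter,
            estimator="robust",
            formula=spec.formula,
            r_squared_is_diagnostic=True,
        )

    def _fit_logistic(self, y_raw: pd.Series, X: pd.DataFrame, spec: ModelSpec) -> FitResult:
        y, levels = _binary_response(y_raw, self.references or {})
        try:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("error", PerfectSeparationWarning)
                res = sm.Logit(y, X.to_numpy()).fit(
                    disp=0, maxiter=200, tol=self.tol, warn_convergence=False
                )
        except (
            PerfectSeparationError,
            PerfectSeparationWarning,
            np.linalg.LinAlgError,
        ) as exc:
            raise SeparationError(f"logistic fit failed: {exc}") from exc
        bse = np.asarray(res.bse, dtype=float)
        if not np.all(np.isfinite(bse)) or np.max(np.abs(res.params)) > 1e3:
            raise SeparationError("logistic fit shows (quasi-)separation")
        return FitResult(
            coefficients=pd.Series(res.params, index=X.columns),
            standard_errors=pd.Series(bse, index=X.columns),
            p_values=pd.Series(res.pvalues, index=X.columns),
            r_squared=None,
            residuals=pd.Series(y - res.predict(X.to_numpy()), index=X.index),
            n_used=len(X),
            converged=bool(res.mle_retvals.get("converged", True)),
            estimator="logistic",
            formula=spec.formula,
            extra={"response_levels": levels},
        )


def _binary_response(y: pd.Series, references: dict) -> tuple[np.ndarray, list]:
    vals = y.dropna().unique().tolist()
    if set(vals) <= {0, 1}:
        if len(vals) < 2:
            raise InvalidInputError("logistic response has a single observed level")
        return y.to_numpy(dtype=float), [0, 1]
    if len(vals) != 2:
        raise InvalidInputError(
            f"logistic response must be binary, observed levels: {vals}"
        )
    if isinstance(y.dtype, pd.CategoricalDtype):
        levels = [lv for lv in y.cat.categories if lv in vals]
    else:
        levels = sorted(vals)
    ref = references.get(y.name)
    if ref in levels:
        levels = [ref] + [lv for lv in levels if lv != ref]
    return (y == levels[1]).to_numpy(dtype=float), levels


# -- thin functional surface ---------------------------------------------


def fit_linear(
    spec: str | ModelSpec,
    data: pd.DataFrame,
    estimator: str = "ols",
    references: dict | None = None,
) -> FitResult:
    """Fit a linear model (OLS or Huber-robust) and return its summary."""
    if estimator not in {"ols", "robust"}:
        raise InvalidInputError(f"fit_linear supports 'ols' or 'robust', got {estimator!r}")
    formula = spec.formula if isinstance(spec, ModelSpec) else spec
    return FormulaRegressor(formula, estimator=estimator, references=references).fit(data).result_


def fit_logistic(
    spec: str | ModelSpec, data: pd.DataFrame, references: dict | None = None
) -> FitResult:
    """Maximum-likelihood logistic fit with Wald p-values."""
    formula = spec.formula if isinstance(spec, ModelSpec) else spec
    return FormulaRegressor(formula, estimator="logistic", references=references).fit(data).result_


def residualize(
    data: pd.DataFrame,
    response: str,
    covariates: str = "1 + age + C(sex)",
    references: dict | None = None,
) -> pd.Series:
    """OLS residuals of ``response`` after regressing on ``covariates``.

    Returns a series aligned to the complete-case rows; residuals are
    orthogonal to every covariate column.
    """
    result = fit_linear(f"{response} ~ {covariates}", data, estimator="ols",
                        references=references)
    return result.residuals.rename(f"{response}_resid")


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise Bonferroni p-value threshold ``alpha / m``."""
    if not 0 < alpha < 1:
        raise InvalidInputError(f"alpha must be in (0,1), got {alpha}")
    if not isinstance(m, (int, np.integer)) or m < 1:
        raise InvalidInputError(f"number of tests must be a positive integer, got {m}")
    return alpha / m
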