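"""Polygenic score computation, filtering, and ranking.

A *weight table* holds per-variant effect-allele weights with genomic
coordinates and discovery p-values (columns ``variant_id chrom pos
effect_allele weight pvalue``).  A raw score is the weighted sum of
effect-allele dosages; the full-table score is referred to as the PRS, the
score restricted to genome-wide significant variants (p < 5e-8) as the GRS.

Conventions, fixed and documented:

* dosages are declared pre-oriented to the effect allele — no allele
  flipping or strand reconciliation happens here;
* standardization uses the analysis cohort's own mean and population (n)
  standard deviation;
* percentile ranks are nearest-rank on the empirical CDF: rank 0 for the
  minimum, ties share the lower rank; deciles are assigned by empirical
  rank with ties broken by stable sample order, so decile sizes differ by
  at most one;
* region exclusion removes variants on the given chromosome whose position
  lies within ``center +/- half_window``, boundary inclusive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import (
    DegenerateScoreError,
    InvalidInputError,
    MissingVariantError,
)

GWS_ALPHA = 5e-8
FTO_WINDOW = 100_000

WEIGHT_COLUMNS = ["variant_id", "chrom", "pos", "effect_allele", "weight", "pvalue"]


def validate_weight_table(weights: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in WEIGHT_COLUMNS if c not in weights.columns]
    if missing:
        raise InvalidInputError(f"weight table lacks columns: {missing}")
    if weights["variant_id"].duplicated().any():
        dups = weights.loc[weights["variant_id"].duplicated(), "variant_id"].tolist()
        raise InvalidInputError(f"duplicate variant_id values: {dups[:10]}")
    if (weights["pos"] < 1).any():
        raise InvalidInputError("positions must be 1-based (>= 1)")
    if not np.isfinite(weights["weight"].to_numpy(dtype=float)).all():
        raise InvalidInputError("weights must be finite")
    pv = weights["pvalue"].to_numpy(dtype=float)
    if ((pv <= 0) | (pv > 1)).any():
        raise InvalidInputError("p-values must lie in (0, 1]")
    return weights


def filter_genomewide_significant(
    weights: pd.DataFrame, alpha: float = GWS_ALPHA
) -> pd.DataFrame:
    """Retain variants with discovery p strictly below ``alpha``.

    The genome-wide threshold is strict: a variant at exactly ``alpha`` is
    excluded.  Record order is preserved.
    """
    if not 0 < alpha <= 1:
        raise InvalidInputError(f"alpha must be in (0, 1], got {alpha}")
    validate_weight_table(weights)
    out = weights.loc[weights["pvalue"] < alpha].copy()
    out.attrs["n_removed"] = len(weights) - len(out)
    return out


def exclude_region(
    weights: pd.DataFrame,
    chromosome: str,
    center: int,
    half_window: int = FTO_WINDOW,
) -> pd.DataFrame:
    """Drop variants within ``center +/- half_window`` on ``chromosome``.

    The window boundary is inclusive.  Used for locus-exclusion sensitivity
    analyses such as removing the FTO region (lead SNP +/- 100 kb) from the
    score.  The number of removed records is stored in ``attrs['n_removed']``.
    """
    if half_window < 0:
        raise InvalidInputError("half_window must be >= 0")
    validate_weight_table(weights)
    chrom = weights["chrom"].astype(str)
    inside = (chrom == str(chromosome)) & (
        (weights["pos"] - int(center)).abs() <= int(half_window)
    )
    out = weights.loc[~inside].copy()
    out.attrs["n_removed"] = int(inside.sum())
    return out


def compute_score(genotypes: pd.DataFrame, weights: pd.DataFrame) -> pd.DataFrame:
    """Weighted sum of effect-allele dosages per sample.

    ``genotypes`` is a samples x variants dosage matrix (index: sample ids,
    columns: variant ids, values in [0, 2]).  Every weight-table variant must
    be present — missing variants raise, they are never silently dropped.
    Returns a :func:`standardize_and_rank` score table; when the raw scores
    are constant (e.g. all weights zero) the raw column is still returned and
    the standardized/ranked columns are NaN.
    """
    validate_weight_table(weights)
    if len(weights) == 0:
        raise InvalidInputError("weight table is empty")
    missing = [v for v in weights["variant_id"] if v not in genotypes.columns]
    if missing:
        raise MissingVariantError(missing)
    dose = genotypes.loc[:, weights["variant_id"].tolist()].to_numpy(dtype=float)
    raw = dose @ weights["weight"].to_numpy(dtype=float)
    try:
        return standardize_and_rank(raw, sample_ids=genotypes.index)
    except DegenerateScoreError:
        return pd.DataFrame(
            {
                "raw_score": raw,
                "standardized_score": np.nan,
                "percentile_rank": np.nan,
                "decile": np.nan,
            },
            index=pd.Index(genotypes.index, name="sample_id"),
        )


def standardize_and_rank(raw, sample_ids=None) -> pd.DataFrame:
    """Standardize raw scores and assign percentile ranks and deciles.

    Returns a frame with columns ``raw_score``, ``standardized_score``
    (z-units within this cohort, population SD), ``percentile_rank``
    (0..99) and ``decile`` (1..10).
    """
    raw = np.asarray(raw, dtype=float)
    n = raw.size
    if n < 2:
        raise InvalidInputError("need at least 2 samples to standardize")
    if not np.isfinite(raw).all():
        raise InvalidInputError("raw scores must be finite")
    sd = raw.std()  # population (ddof=0)
    if sd == 0:
        raise DegenerateScoreError("raw scores have zero variance")
    z = (raw - raw.mean()) / sd

    sorted_scores = np.sort(raw)
    n_less = np.searchsorted(sorted_scores, raw, side="left")
    percentile = (100 * n_less) // n

    order = np.argsort(raw, kind="stable")
    position = np.empty(n, dtype=int)
    position[order] = np.arange(n)
    decile = position * 10 // n + 1

    if sample_ids is None:
        sample_ids = pd.RangeIndex(n)
    return pd.DataFrame(
        {
            "raw_score": raw,
            "standardized_score": z,
            "percentile_rank": percentile,
            "decile": decile,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )


class PolygenicScorer(BaseEstimator, TransformerMixin):
    """Dosages -> standardized polygenic score, as an sklearn transformer.

    Parameters
    ----------
    weights:
        Weight table (``variant_id chrom pos effect_allele weight pvalue``).
    gws_only:
        Restrict to genome-wide significant variants (p < ``gws_alpha``),
        i.e. compute a GRS instead of the full PRS.
    gws_alpha:
        Significance threshold for ``gws_only``.
    exclude_regions:
        Iterable of ``(chromosome, center, half_window)`` windows to drop
        before scoring (locus-exclusion sensitivity analysis).

    ``fit`` learns the scoring cohort's mean/SD; ``transform`` returns
    standardized scores for (possibly new) dosage matrices on that scale.
    """

    def __init__(self, weights=None, gws_only=False, gws_alpha=GWS_ALPHA, exclude_regions=()):
        self.weights = weights
        self.gws_only = gws_only
        self.gws_alpha = gws_alpha
        self.exclude_regions = exclude_regions

    def _effective_weights(self) -> pd.DataFrame:
        if self.weights is None:
            raise InvalidInputError("PolygenicScorer requires a weight table")
        w = validate_weight_table(self.weights)
        if self.gws_only:
            w = filter_genomewide_significant(w, self.gws_alpha)
        for chrom, center, half in self.exclude_regions:
            w = exclude_region(w, chrom, center, half)
        if len(w) == 0:
            raise InvalidInputError("no variants left after filtering")
        return w

    def fit(self, X: pd.DataFrame, y=None) -> "PolygenicScorer":
        self.weights_used_ = self._effective_weights()
        scores = compute_score(X, self.weights_used_)
        self.mean_ = float(scores["raw_score"].mean())
        self.sd_ = float(scores["raw_score"].std(ddof=0))
        if self.sd_ == 0:
            raise DegenerateScoreError("raw scores have zero variance")
        self.n_variants_ = len(self.weights_used_)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        missing = [v for v in self.weights_used_["variant_id"] if v not in X.columns]
        if missing:
            raise MissingVariantError(missing)
        dose = X.loc[:, self.weights_used_["variant_id"].tolist()].to_numpy(dtype=float)
        raw = dose @ self.weights_used_["weight"].to_numpy(dtype=float)
        return pd.DataFrame(
            {"raw_score": raw, "standardized_score": (raw - self.mean_) / self.sd_},
            index=pd.Index(X.index, name="sample_id"),
        )

    def score_vector(self, X: pd.DataFrame) -> pd.DataFrame:
        """Full score table (raw, z, percentile, decile) for cohort ``X``."""
        w = self._effective_weights()
        return compute_score(X, w)
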