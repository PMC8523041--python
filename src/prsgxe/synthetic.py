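"""Synthetic cohort generator.

Emulates the data structure of a middle-aged population cohort in which a
standardized BMI polygenic score (PRS), age, sex, a set of behavioral risk
factors, and gene-environment interaction terms jointly generate BMI:

    BMI = intercept + beta_age*age + beta_sex*1[male] + beta_prs*PRS
        + beta_activity*1[inactive] + beta_linear_int*PRS*1[inactive]
        + beta_threshold_int*1[inactive]*1[PRS > q(threshold_percentile)]
        + risk-factor offsets + eps,   eps ~ N(0, sigma_noise^2)

Sign convention: active individuals have lower BMI, so the positive
activity/interaction coefficients are applied to the *inactive* group and
reported interaction magnitudes map directly onto generator parameters.

The threshold indicator uses a strict ``>`` on the empirical percentile of
the generated PRS, matching the indicator used by the downstream cut-off
search.

A single master seed spawns independent substreams per component (weight
table, genotypes, phenotypes, noise) so components can be regenerated
independently and reproducibly.

The generator's defaults describe a discovery cohort with objectively
measured BMI; :func:`replication_config` switches to a self-report cohort
(reporting bias on height/weight, wider age range, three-level activity
labels).  Because the real cohorts' BMI mean/SD and age distributions are
not published, the intercept/age defaults are calibrated placeholders —
chosen so the PRS explains ~13% of BMI variance and age+sex a few percent —
and are documented as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import InvalidConfigError, InvalidInputError
from .scoring import GWS_ALPHA, standardize_and_rank

# substream indices under the master seed
_SS_WEIGHTS, _SS_GENOTYPES, _SS_PHENOTYPES, _SS_NOISE = range(4)

ACTIVITY_THRESHOLD_MIN_WEEK = 225.0
ALCOHOL_LIMIT = {"female": 6.0, "male": 12.0}
DQS_HEALTHY_MIN = 9

SMOKING_CATEGORIES = [
    "never smoker",
    "previous smoker",
    "smoking occasionally",
    "smoking daily",
]
SOCIOECONOMIC_CATEGORIES = [
    "working, >= 4 years of education",
    "working, 1-3 years of education",
    "working, no education",
    "not working, >= 1 year of education",
    "not working, no education",
]


def default_risk_factor_specs() -> dict:
    """Category probabilities and BMI offsets for the six non-activity factors.

    Offsets follow the reported per-category association scale; prevalences
    are round numbers of the same order as the per-factor sample sizes of a
    questionnaire-based population cohort.
    """
    return {
        "smoking": {
            "categories": list(SMOKING_CATEGORIES),
            "probs": [0.35, 0.27, 0.08, 0.30],
            "effects": [0.0, 0.06, 0.27, -1.06],
        },
        "alcohol": {
            "gamma_shape": 2.0,
            "mean_units": {"female": 3.0, "male": 7.0},
            "effect_high": -0.36,
        },
        "diet": {"dqs_min": 4, "dqs_max": 12, "healthy_prob": 0.35, "effect_poor": -0.25},
        "mental_health": {"mcs_mean": 50.0, "mcs_sd": 10.0, "effect_low": -0.06},
        "sleep": {"insomnia_prob": 0.20, "effect_poor": 0.15},
        "socioeconomic": {
            "working_prob": 0.75,
            "education_probs": {"no education": 0.15, "1-3 years": 0.35, ">= 4 years": 0.50},
            "effects": {
                "working, >= 4 years of education": 0.0,
                "working, 1-3 years of education": 0.0,
                "working, no education": 0.21,
                "not working, >= 1 year of education": 0.18,
                "not working, no education": 0.01,
            },
        },
    }


@dataclass
class ReportingBias:
    """Self-report bias: height over-reported, weight under-reported."""

    height_mean_cm: float = 1.5
    height_sd_cm: float = 1.5
    weight_mean_kg: float = 1.5
    weight_sd_kg: float = 2.0


@dataclass
class SimulationConfig:
    """Full generative-model parameterization for one synthetic cohort."""

    n_samples: int = 5179
    n_snps: int = 500
    maf_range: tuple = (0.05, 0.5)
    seed: int = 0
    significant_fraction: float = 0.1
    lead_chrom: str = "16"
    lead_pos: int = 53_820_000
    intercept: float = 24.0  # kg/m^2; placeholder, see module docstring
    age_range: tuple = (30.0, 60.0)  # years
    beta_age: float = 0.04  # kg/m^2 per year
    beta_sex: float = 1.0  # kg/m^2 offset for males
    beta_prs: float = 1.56  # kg/m^2 per standardized PRS unit
    beta_activity: float = 0.79  # kg/m^2, inactive vs active
    beta_linear_int: float = 0.0  # kg/m^2 per SD of PRS, inactive only
    beta_threshold_int: float = 0.0  # extra inactive-vs-active gap above cut-off
    threshold_percentile: Optional[int] = None
    sigma_noise: float = 3.9  # kg/m^2
    inactive_prevalence: float = 0.33
    risk_factor_specs: dict = field(default_factory=default_risk_factor_specs)
    n_traits: int = 20
    trait_loadings: Optional[tuple] = None  # ((slope, noise_sd), ...) per trait
    n_gpcs: int = 3
    reporting_bias: Optional[ReportingBias] = None
    three_level_activity: bool = False

    def __post_init__(self):
        if self.n_samples < 1:
            raise InvalidConfigError("n_samples must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise InvalidConfigError("maf_range must lie within (0, 0.5]")
        if self.sigma_noise <= 0:
            raise InvalidConfigError("sigma_noise must be > 0")
        for name in ("significant_fraction", "inactive_prevalence"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InvalidConfigError(f"{name} must be in [0, 1], got {v}")
        if self.threshold_percentile is not None:
            tp = self.threshold_percentile
            if not (isinstance(tp, (int, np.integer)) and 0 <= tp <= 99):
                raise InvalidConfigError(
                    f"threshold_percentile must be an integer in [0, 99], got {tp!r}"
                )
        if self.age_range[0] >= self.age_range[1] or self.age_range[0] <= 0:
            raise InvalidConfigError("age_range must be increasing and positive")

    def substream(self, which: int) -> np.random.Generator:
        children = np.random.SeedSequence(self.seed).spawn(4)
        return np.random.default_rng(children[which])

    def effective_trait_loadings(self) -> tuple:
        if self.trait_loadings is not None:
            if len(self.trait_loadings) != self.n_traits:
                raise InvalidConfigError("trait_loadings length must equal n_traits")
            return tuple(self.trait_loadings)
        return tuple((0.5, 1.0) for _ in range(self.n_traits))


def replication_config(**overrides) -> SimulationConfig:
    """Self-report replication-cohort preset (n=3,415, ages 20-60).

    Height/weight are self-reported with a mild systematic bias and age
    carries more of the BMI variance than in the discovery preset, the
    pattern observed when anthropometrics come from questionnaires.
    """
    base = dict(
        n_samples=3415,
        age_range=(20.0, 60.0),
        beta_age=0.17,
        beta_sex=1.5,
        reporting_bias=ReportingBias(),
        three_level_activity=True,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def discovery_config(**overrides) -> SimulationConfig:
    """Objectively-measured discovery-cohort preset (n=5,179, ages 30-60)."""
    return SimulationConfig(**overrides)


# -- generators -----------------------------------------------------------


def generate_weight_table(config: SimulationConfig) -> pd.DataFrame:
    """Draw a per-variant weight table with discovery p-values.

    Exactly ``round(significant_fraction * n_snps)`` variants receive
    p < 5e-8 (assigned deterministically by rank of a uniform draw), so
    genome-wide-significance filtering is non-trivial.  One designated lead
    variant at ``(lead_chrom, lead_pos)`` is always present (and always
    significant) to exercise region exclusion.
    """
    if config.n_snps < 1:
        raise InvalidConfigError("n_snps must be >= 1")
    rng = config.substream(_SS_WEIGHTS)
    n = config.n_snps
    chroms = [str(c) for c in (np.arange(n) % 22 + 1)]
    positions = np.zeros(n, dtype=int)
    for c in set(chroms):
        idx = [i for i, ch in enumerate(chroms) if ch == c]
        pos = np.sort(rng.choice(np.arange(1, 50_000_000), size=len(idx), replace=False))
        positions[idx] = pos
    alleles = rng.choice(list("ACGT"), size=n)
    weights = rng.normal(0.0, 0.02, size=n)

    n_sig = int(round(config.significant_fraction * n))
    n_sig = max(n_sig, 1)  # the lead variant is always significant
    rank_draw = rng.random(n)
    sig_idx = np.argsort(rank_draw, kind="stable")[:n_sig]
    pvalues = rng.uniform(GWS_ALPHA, 1.0, size=n)
    pvalues[sig_idx] = GWS_ALPHA * 10.0 ** (-rng.uniform(0.1, 10.0, size=n_sig))

    table = pd.DataFrame(
        {
            "variant_id": [f"rs{i + 1:06d}" for i in range(n)],
            "chrom": chroms,
            "pos": positions,
            "effect_allele": alleles,
            "weight": weights,
            "pvalue": pvalues,
        }
    )
    # the designated lead variant is one of the significant records, so the
    # significant count stays exactly n_sig
    lead_row = int(sig_idx[0])
    table.loc[lead_row, ["variant_id", "chrom", "pos"]] = [
        "lead_snp",
        str(config.lead_chrom),
        config.lead_pos,
    ]
    table.loc[lead_row, "weight"] = abs(table.loc[lead_row, "weight"]) + 0.02
    table = table.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    # enforce strictly increasing positions within chromosome
    for c in table["chrom"].unique():
        sel = table["chrom"] == c
        pos = table.loc[sel, "pos"].to_numpy()
        for i in range(1, len(pos)):
            if pos[i] <= pos[i - 1]:
                pos[i] = pos[i - 1] + 1
        table.loc[sel, "pos"] = pos
    return table


def generate_genotypes(config: SimulationConfig, weights: pd.DataFrame) -> pd.DataFrame:
    """Hardy-Weinberg dosages: per-variant binomial(2, maf), maf ~ U(maf_range)."""
    if len(weights) == 0:
        raise InvalidInputError("weight table is empty")
    rng = config.substream(_SS_GENOTYPES)
    lo, hi = config.maf_range
    mafs = rng.uniform(lo, hi, size=len(weights))
    dosages = rng.binomial(2, mafs, size=(config.n_samples, len(weights))).astype(float)
    sample_ids = [f"S{i + 1:06d}" for i in range(config.n_samples)]
    return pd.DataFrame(
        dosages,
        index=pd.Index(sample_ids, name="sample_id"),
        columns=weights["variant_id"].tolist(),
    )


def _check_standardized(prs: np.ndarray) -> None:
    if abs(prs.mean()) > 1e-6 or abs(prs.std() - 1.0) > 1e-6:
        raise InvalidInputError(
            "PRS must be standardized (mean 0, SD 1) before cohort generation; "
            f"got mean={prs.mean():.4g}, sd={prs.std():.4g}"
        )


def generate_cohort(config: SimulationConfig, prs) -> pd.DataFrame:
    """Generate a phenotype cohort on top of a standardized PRS vector.

    Returns a frame with BMI, age, sex, raw risk-factor measures, genetic
    PCs, BMI-correlated auxiliary traits, and the PRS column itself (plus
    its percentile rank and decile).  When ``config.reporting_bias`` is set,
    height/weight are emitted as self-reported values and the ``bmi`` column
    is recomputed from them (the unbiased value is kept as ``bmi_true``).
    """
    if hasattr(prs, "columns") and "standardized_score" in getattr(prs, "columns", []):
        prs = prs["standardized_score"].to_numpy()
    prs = np.asarray(prs, dtype=float)
    if prs.size != config.n_samples:
        raise InvalidInputError(
            f"PRS length {prs.size} != n_samples {config.n_samples}"
        )
    _check_standardized(prs)
    rng = config.substream(_SS_PHENOTYPES)
    noise_rng = config.substream(_SS_NOISE)
    n = config.n_samples
    specs = config.risk_factor_specs
    warnings: list[str] = []

    age = rng.uniform(*config.age_range, size=n)
    male = rng.random(n) < 0.5
    sex = np.where(male, "male", "female")

    inactive = rng.random(n) < config.inactive_prevalence
    minutes = np.where(
        inactive,
        rng.uniform(0.0, ACTIVITY_THRESHOLD_MIN_WEEK, size=n),
        rng.uniform(ACTIVITY_THRESHOLD_MIN_WEEK + 1.0, 840.0, size=n),
    )

    smoking_spec = specs["smoking"]
    smoking = rng.choice(smoking_spec["categories"], size=n, p=smoking_spec["probs"])
    smoking_effect = pd.Series(smoking).map(
        dict(zip(smoking_spec["categories"], smoking_spec["effects"]))
    ).to_numpy()

    alc = specs["alcohol"]
    mean_units = np.where(male, alc["mean_units"]["male"], alc["mean_units"]["female"])
    units = rng.gamma(alc["gamma_shape"], mean_units / alc["gamma_shape"], size=n)
    limit = np.where(male, ALCOHOL_LIMIT["male"], ALCOHOL_LIMIT["female"])
    alcohol_effect = np.where(units > limit, alc["effect_high"], 0.0)

    diet = specs["diet"]
    poor_levels = np.arange(diet["dqs_min"], DQS_HEALTHY_MIN)
    healthy_levels = np.arange(DQS_HEALTHY_MIN, diet["dqs_max"] + 1)
    probs = np.concatenate(
        [
            np.full(len(poor_levels), (1 - diet["healthy_prob"]) / len(poor_levels)),
            np.full(len(healthy_levels), diet["healthy_prob"] / len(healthy_levels)),
        ]
    )
    dqs = rng.choice(np.concatenate([poor_levels, healthy_levels]), size=n, p=probs)
    diet_effect = np.where(dqs < DQS_HEALTHY_MIN, diet["effect_poor"], 0.0)

    mh = specs["mental_health"]
    mcs = rng.normal(mh["mcs_mean"], mh["mcs_sd"], size=n)
    mh_effect = np.zeros(n)
    for s in ("female", "male"):
        sel = sex == s
        if sel.any():
            q75 = np.percentile(mcs[sel], 75)
            mh_effect[sel] = np.where(mcs[sel] > q75, 0.0, mh["effect_low"])

    sleep = specs["sleep"]
    insomnia = np.where(rng.random(n) < sleep["insomnia_prob"], "yes", "no")
    sleep_effect = np.where(insomnia == "yes", sleep["effect_poor"], 0.0)

    soc = specs["socioeconomic"]
    working = rng.random(n) < soc["working_prob"]
    edu_levels = list(soc["education_probs"])
    education = rng.choice(edu_levels, size=n, p=list(soc["education_probs"].values()))
    soc_label = np.where(
        working,
        np.char.add("working, ", np.where(education == "no education",
                                          "no education",
                                          np.char.add(education.astype(str), " of education"))),
        np.where(education == "no education",
                 "not working, no education",
                 "not working, >= 1 year of education"),
    )
    soc_effect = pd.Series(soc_label).map(soc["effects"]).to_numpy()

    gpcs = rng.standard_normal((n, config.n_gpcs))

    threshold_term = np.zeros(n)
    if config.threshold_percentile is not None:
        q = np.percentile(prs, config.threshold_percentile)
        above = prs > q
        threshold_term = config.beta_threshold_int * (inactive & above)
        if config.beta_threshold_int != 0 and (
            above.sum() < 2 or (~above).sum() < 2
        ):
            warnings.append(
                "degenerate threshold design: fewer than 2 samples on one side"
            )

    eps = noise_rng.normal(0.0, config.sigma_noise, size=n)
    bmi = (
        config.intercept
        + config.beta_age * age
        + config.beta_sex * male
        + config.beta_prs * prs
        + config.beta_activity * inactive
        + config.beta_linear_int * prs * inactive
        + threshold_term
        + smoking_effect
        + alcohol_effect
        + diet_effect
        + mh_effect
        + sleep_effect
        + soc_effect
        + eps
    )

    cohort = pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:06d}" for i in range(n)],
            "bmi": bmi,
            "age": age,
            "sex": pd.Categorical(sex, categories=["female", "male"]),
            "smoking_status": pd.Categorical(smoking, categories=SMOKING_CATEGORIES),
            "alcohol_units_week": units,
            "dqs": dqs.astype(int),
            "mcs": mcs,
            "insomnia": insomnia,
            "employment": np.where(working, "working", "not working"),
            "education": education,
        }
    )
    if config.three_level_activity:
        high_job = rng.random(n) < 0.4
        cohort["activity_level"] = np.where(
            inactive, "sedentary", np.where(high_job, "high", "moderate")
        )
    else:
        cohort["activity_min_week"] = minutes
    for k in range(config.n_gpcs):
        cohort[f"gpc{k + 1}"] = gpcs[:, k]
    for j, (slope, nsd) in enumerate(config.effective_trait_loadings()):
        cohort[f"trait_{j + 1}"] = slope * bmi + noise_rng.normal(0.0, nsd, size=n)

    if config.reporting_bias is not None:
        rb = config.reporting_bias
        height = np.where(male, rng.normal(179.0, 7.0, n), rng.normal(166.0, 6.0, n))
        weight = bmi * (height / 100.0) ** 2
        rep_height = height + rng.normal(rb.height_mean_cm, rb.height_sd_cm, n)
        rep_weight = np.maximum(weight - rng.normal(rb.weight_mean_kg, rb.weight_sd_kg, n), 30.0)
        cohort["height_cm"] = rep_height
        cohort["weight_kg"] = rep_weight
        cohort["bmi_true"] = bmi
        cohort["bmi"] = rep_weight / (rep_height / 100.0) ** 2

    ranks = standardize_and_rank(prs)
    cohort["prs"] = prs
    cohort["prs_percentile"] = ranks["percentile_rank"].to_numpy()
    cohort["prs_decile"] = ranks["decile"].to_numpy()
    cohort = cohort.set_index("sample_id")
    cohort.attrs["warnings"] = warnings
    cohort.attrs["config_seed"] = config.seed
    return cohort


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Cohort with a directly drawn (exactly standardized) PRS.

    Skips genotype generation; the genetic component is a standard-normal
    draw z-scored to mean 0 / SD 1, appropriate for analyses that never
    touch individual variants.
    """
    rng = config.substream(_SS_GENOTYPES)
    raw = rng.standard_normal(config.n_samples)
    prs = (raw - raw.mean()) / raw.std()
    return generate_cohort(config, prs)


def simulate_study(config: SimulationConfig) -> dict:
    """Full generative path: weight table -> genotypes -> PRS -> cohort.

    Returns ``{"weights", "genotypes", "scores", "cohort"}`` where the
    cohort's BMI was generated from the genotype-derived standardized PRS.
    """
    weights = generate_weight_table(config)
    genotypes = generate_genotypes(config, weights)
    from .scoring import compute_score  # local import to avoid cycle at import time

    scores = compute_score(genotypes, weights)
    cohort = generate_cohort(config, scores["standardized_score"].to_numpy())
    return {"weights": weights, "genotypes": genotypes, "scores": scores, "cohort": cohort}


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of ``config`` with a new master seed."""
    return replace(config, seed=int(seed))
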