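import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from prsgxe.association import categorize_risk_factors
from prsgxe.synthetic import discovery_config, simulate_cohort

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_weights():
    """Five-variant weight table with known coordinates and p-values."""
    return pd.DataFrame(
        {
            "variant_id": ["v1", "v2", "v3", "v4", "v5"],
            "chrom": ["1", "1", "2", "16", "16"],
            "pos": [100, 5000, 100, 900_000, 1_500_000],
            "effect_allele": ["A", "C", "G", "T", "A"],
            "weight": [0.5, -0.2, 0.1, 0.3, -0.4],
            "pvalue": [1e-10, 5e-8, 0.2, 4.9e-8, 0.9],
        }
    )


@pytest.fixture(scope="session")
def tiny_genotypes(tiny_weights):
    rng = np.random.default_rng(11)
    dose = rng.integers(0, 3, size=(6, 5)).astype(float)
    return pd.DataFrame(
        dose,
        index=pd.Index([f"S{i}" for i in range(6)], name="sample_id"),
        columns=tiny_weights["variant_id"].tolist(),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Categorized synthetic cohort with a linear interaction signal."""
    cfg = discovery_config(
        n_samples=1200, seed=42, beta_activity=0.8, beta_linear_int=0.4, n_traits=3
    )
    return categorize_risk_factors(simulate_cohort(cfg))


@pytest.fixture(scope="session")
def threshold_cohort():
    """Categorized cohort generated with a threshold interaction at the 50th percentile."""
    cfg = discovery_config(
        n_samples=1500,
        seed=7,
        beta_activity=0.65,
        beta_threshold_int=2.0,
        threshold_percentile=50,
        n_traits=0,
    )
    return categorize_risk_factors(simulate_cohort(cfg))
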