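import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import rnaclock as rc

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cohort():
    """A shared 4-batch, 100-sample cohort with moderate age signal."""
    cfg = rc.SimulationConfig(
        n_batches=4,
        samples_per_batch=25,
        n_genes=200,
        n_age_genes=60,
        age_slope_sd=0.02,
        batch_shift_sd=0.6,
        seed=42,
    )
    counts, meta, truth = rc.simulate_cohort(cfg)
    return cfg, counts, meta, truth


@pytest.fixture(scope="session")
def small_corrected(small_cohort):
    """The shared cohort pushed through TMM + log2 CPM + batch correction."""
    _, counts, meta, _ = small_cohort
    factors = rc.tmm_factors(counts)
    norm = rc.normalize_log2(counts, factors)
    corrected, model = rc.fit_combat(norm, meta)
    return norm, corrected, model


@pytest.fixture(scope="session")
def small_clock(small_cohort, small_corrected):
    """A quick clock trained on the shared cohort's top variable genes."""
    _, _, meta, _ = small_cohort
    _, corrected, _ = small_corrected
    genes = rc.top_variable_genes(corrected, 50)
    return rc.train_clock(
        corrected,
        meta["age"],
        gene_set=genes,
        folds=5,
        repeats=1,
        trees=80,
        seed=7,
    )


def random_count_table(rng, n_genes, n_samples, depth_spread=0.3):
    """Poisson counts around lognormal gene means with per-sample depth."""
    mu = np.exp(rng.normal(4.0, 1.5, n_genes))
    depth = np.exp(rng.normal(0.0, depth_spread, n_samples))
    counts = rng.poisson(mu[:, None] * depth[None, :])
    return pd.DataFrame(
        counts,
        index=[f"g{i:04d}" for i in range(n_genes)],
        columns=[f"s{j:02d}" for j in range(n_samples)],
    )
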