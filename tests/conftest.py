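import numpy as np
import pytest

from ashmscan.simulate import (
    CohortConfig,
    build_toy_genome,
    filtered_cohort,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def toy_genome():
    return build_toy_genome(seed=7)


@pytest.fixture(scope="session")
def small_genome():
    return build_toy_genome(
        chromosomes=(("chr1", 2_000_000),), n_genes=12, n_se_genes=2, seed=11
    )


@pytest.fixture(scope="session")
def enriched_sim(toy_genome):
    """Fold-10 enriched cohort at default config, with its truth ledger."""
    config = CohortConfig(
        n_patients=8, se_promoter_enrichment=10.0, gain_probability_dhl=0.75, seed=3
    )
    return simulate_cohort(toy_genome, config)


@pytest.fixture(scope="session")
def enriched_cohort(enriched_sim):
    return filtered_cohort(enriched_sim)


@pytest.fixture(scope="session")
def null_sim(small_genome):
    config = CohortConfig(n_patients=4, se_promoter_enrichment=1.0, seed=5)
    return simulate_cohort(small_genome, config)


@pytest.fixture(scope="session")
def null_cohort(null_sim):
    return filtered_cohort(null_sim)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
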