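import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from eqtl_enrich import (
    SyntheticConfig,
    assign_maf_bins,
    compute_scores,
    generate_world,
    summarize_eqtls,
)

settings.register_profile(
    "default",
    derandomize=True,
    database=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


SMALL_WORLD_CONFIG = SyntheticConfig(
    n_snps=2000,
    n_genes=60,
    n_catalog=100,
    n_chrom=4,
    chrom_length=30_000_000,
    seed=7,
)


@pytest.fixture(scope="session")
def small_world():
    """A compact world with planted enrichment, shared across tests."""
    return generate_world(SMALL_WORLD_CONFIG)


@pytest.fixture(scope="session")
def small_world_summaries(small_world):
    summaries = summarize_eqtls(
        small_world.eqtl,
        small_world.genes,
        small_world.panel,
        n_total=small_world.config.n_genes,
    )
    return {s.rsid: s for s in summaries}


@pytest.fixture(scope="session")
def small_world_scores(small_world_summaries):
    return {
        r.rsid: r.score for r in compute_scores(list(small_world_summaries.values()))
    }


@pytest.fixture(scope="session")
def small_world_bins(small_world):
    return assign_maf_bins(small_world.panel)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
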