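import numpy as np
import pytest

from sorc import SimConfig, prepare, simulate_cohort, simulate_phenotypes


@pytest.fixture(scope="session")
def small_sim():
    """A compact simulated cohort with two functional genes."""
    cfg = SimConfig(
        n_individuals=250,
        n_genes=10,
        variants_per_gene=(3, 8),
        functional_genes=2,
        functional_variants_per_gene=2,
        n_phenotype_replicates=3,
        seed=11,
    )
    g, genemap, variants, truth = simulate_cohort(cfg)
    phenotypes = simulate_phenotypes(g, truth, cfg.noise_sd, 3, seed=12)
    return g, genemap, variants, truth, phenotypes


@pytest.fixture(scope="session")
def small_cohort(small_sim):
    g, genemap, variants, _, _ = small_sim
    return prepare(g, genemap, variants)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
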