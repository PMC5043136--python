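import numpy as np
import pytest

from duphist.simulate import SimConfig, build_ancestral_genome


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_catalog():
    """One chromosome, 12 genes, 2 family members."""
    cfg = SimConfig(n_chromosomes=1, genes_per_chromosome=12,
                    family_founder_count=2, seed=11)
    return build_ancestral_genome(cfg, species="sp")


@pytest.fixture(scope="session")
def medium_catalog():
    """Two chromosomes, 25 genes each, 2 family members."""
    cfg = SimConfig(n_chromosomes=2, genes_per_chromosome=25,
                    family_founder_count=2, seed=5)
    return build_ancestral_genome(cfg, species="sp")
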