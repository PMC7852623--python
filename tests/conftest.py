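import numpy as np
import pytest

from cytogxe.synthetic import (GeneSnpSpec, GenotypeSimSpec,
                               simulate_cohort, simulate_genotypes)


@pytest.fixture(scope="session")
def small_cohort():
    """200-dyad cohort with no planted exclusions."""
    return simulate_cohort(200, seed=11)


@pytest.fixture(scope="session")
def small_genotypes():
    """200 subjects, one 6-SNP gene with moderate LD, complete calls."""
    return simulate_genotypes(GenotypeSimSpec(
        n_subjects=200,
        genes=[GeneSnpSpec("TNFRSF19", 6, (0.1, 0.5), 0.4)],
        missing_rate=0.0, seed=12))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
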