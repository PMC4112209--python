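import numpy as np
import pytest

from tepop.evidence import ExactReadAligner
from tepop.synthetic import (
    SpeciesProfile, build_reference, simulate_population, simulate_sites,
)


@pytest.fixture(scope="session")
def small_bundle():
    """A 100-kb single-chromosome reference with the default TE library."""
    return build_reference(chrom_length=100_000, n_genes=10, seed=1)


@pytest.fixture(scope="session")
def small_sites(small_bundle):
    return simulate_sites(small_bundle, 10, seed=2)


@pytest.fixture(scope="session")
def aligner(small_bundle):
    return ExactReadAligner(small_bundle)


@pytest.fixture(scope="session")
def selfing_population(small_bundle, small_sites):
    profile = SpeciesProfile("selfer", "selfing", 4,
                             site_frequency_model=("beta", 2, 0.5))
    return simulate_population(small_bundle, profile, sites=small_sites, seed=3)


@pytest.fixture(scope="session")
def outcrossing_population(small_bundle, small_sites):
    profile = SpeciesProfile("outx", "outcrossing", 6,
                             site_frequency_model=("beta", 2, 2))
    return simulate_population(small_bundle, profile, sites=small_sites, seed=4)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
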