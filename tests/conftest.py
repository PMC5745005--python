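import numpy as np
import pytest

from locuscope import (
    GenomicWindow,
    SyntheticCohortSpec,
    SyntheticLocusSpec,
    simulate_cohort,
    simulate_locus_reads,
)


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def window():
    return GenomicWindow("chrX", 1000, 6000, "toy")


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort: 34 cell types, one planted 4-bin promoter block."""
    return simulate_cohort(SyntheticCohortSpec(seed=11))


@pytest.fixture(scope="session")
def locus_sim():
    """Default toy-locus read simulation: error-free for exact-geometry checks."""
    return simulate_locus_reads(SyntheticLocusSpec(seed=11, error_rate=0.0))
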