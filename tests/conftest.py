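import numpy as np
import pytest
from hypothesis import settings

from tigmap import (CrossConfig, GenomeModel, Chromosome, default_genome,
                    simulate_f2, simulate_nrbc, pairwise_estimates)

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study_genome():
    """12 chromosomes spanning 19-32 cM, 190 markers (study scale)."""
    return default_genome()


@pytest.fixture(scope="session")
def f2_clean(study_genome):
    """Clean 250-individual F2 simulation at the study scale."""
    return simulate_f2(study_genome, CrossConfig(rng_seed=2011))


@pytest.fixture(scope="session")
def nrbc_clean(study_genome):
    return simulate_nrbc(study_genome, CrossConfig(rng_seed=2011))


@pytest.fixture(scope="session")
def pairwise_clean(f2_clean):
    return pairwise_estimates(f2_clean)


@pytest.fixture(scope="session")
def fitted(f2_clean):
    from tigmap.model import LinkageMapModel
    return LinkageMapModel(f2_clean).fit()


@pytest.fixture
def two_marker_genome():
    """Two markers 10 cM apart on one chromosome."""
    return GenomeModel([Chromosome("c1", ["m1", "m2"],
                                   np.array([0.0, 10.0]))])
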