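import numpy as np
import pytest

from ervrates.kmers import GenomeSequence
from ervrates.simulate import gen_genome, gen_singletons, make_truth


@pytest.fixture(scope="session")
def genome():
    """200-kb single-contig synthetic reference, 40% GC."""
    return gen_genome(200_000, gc_fraction=0.4, n_contigs=1, seed=11)


@pytest.fixture(scope="session")
def truth():
    return make_truth(seed=7)


@pytest.fixture(scope="session")
def singletons(genome, truth):
    """Cohort of 40 samples' singletons drawn from the forward model."""
    return gen_singletons(genome, truth, n_samples=40, seed=13)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def tiny_genome():
    return GenomeSequence.from_strings(
        {"chrA": "ATACGCATTTGGAACGTACGTAGCTAGCATCG",
         "chrB": "GGGCCCATATATATACGCGN" + "ACGT" * 5})
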