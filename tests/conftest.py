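import numpy as np
import pytest

from ampliplate.align import TargetLocus
from ampliplate.primers import default_scheme


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def toy_locus():
    """Small fixed locus for alignment/variant tests."""
    seq = "ACGTACGTAAAACCGGTTACGTACGTGCATGCAT"
    return TargetLocus(
        name="toy",
        chrom="chrT",
        start=100,
        end=100 + len(seq),
        reference_amplicon=seq,
        regions_of_interest=(("gRNA", 8, 20),),
        donor_diffs=((12, "C", "T"),),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
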