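import numpy as np
import pytest

from hybridzone.io import GenotypeMatrix
from hybridzone.simulate import generate_parental_populations, simulate_hybrid_classes


@pytest.fixture(scope="session")
def diagnostic_pops():
    """Two parental populations fully diagnostic at all 12 loci."""
    return generate_parental_populations(
        n_loci=12, alleles_per_locus=4, divergence=1.0, seed=11
    )


@pytest.fixture(scope="session")
def small_classes(diagnostic_pops):
    """100 simulated individuals per class on the diagnostic panel."""
    pop_p, pop_w = diagnostic_pops
    return simulate_hybrid_classes(pop_p, pop_w, 100, seed=13)


@pytest.fixture()
def tiny_matrix():
    calls = np.array(
        [
            [["171", "175"], ["200", "200"]],
            [["171", "171"], [None, None]],
        ],
        dtype=object,
    )
    return GenotypeMatrix(["i1", "i2"], ["loc1", "loc2"], ["MS01", "MS02"], calls)
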