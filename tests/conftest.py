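import numpy as np
import pytest

import mosaicscan as ms


@pytest.fixture(scope="session")
def mosaic_truth():
    """One default two-allele mosaic simulation shared across tests."""
    return ms.simulate_mosaic(ms.SeqSimConfig(n_strains=24, donor_divergence=0.3, seed=42))


@pytest.fixture(scope="session")
def small_quartet():
    """A fixed 4-taxon tree pair with hand-computable K score."""
    ref = ms.PhyloTree.from_newick("((A:0.1,B:0.1):0.1,C:0.1,D:0.1);")
    comp = ms.PhyloTree.from_newick("((A:0.1,C:0.1):0.1,B:0.1,D:0.1);")
    return ref, comp


def spawn_seeds(master: int, n: int) -> np.ndarray:
    """Independent integer sub-seeds derived from one master seed."""
    rng = np.random.default_rng(master)
    return rng.integers(0, 2**31 - 1, size=n)
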