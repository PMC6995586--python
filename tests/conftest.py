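import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from sodnet import synthetic


@pytest.fixture(scope="session")
def potts_standard():
    """The standard planted-coupling benchmark: L=50, q=8, 10 disjoint
    pairs of strength 1.5, M=4000 Gibbs samples, fixed seed."""
    pairs = synthetic.plant_random_pairs(50, 10, 1.5, seed=7)
    spec = synthetic.PottsSpec(
        L=50, q=8, M=4000, n_sweeps=50, planted_pairs=pairs, seed=7
    )
    aln, truth = synthetic.sample_potts_msa(spec)
    return aln, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
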