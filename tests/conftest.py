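from pathlib import Path

import numpy as np
import pytest

from dtirvm import PSSM, SyntheticSpec, gen_network, gen_pssm

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture
def random_pssm() -> PSSM:
    return gen_pssm(5, seed=42, protein_id="p5")


@pytest.fixture
def small_network():
    """5 x 5 bipartite network with 5 positive edges."""
    return gen_network(SyntheticSpec(seed=1, n_drugs=5, n_targets=5, n_positive=5))


@pytest.fixture
def blob_data():
    """Two well-separated 2-d Gaussian blobs, n=40 (20 per class), seed 7."""
    rng = np.random.default_rng(7)
    X = np.vstack([rng.normal(-3.0, 1.0, (20, 2)), rng.normal(3.0, 1.0, (20, 2))])
    y = np.array([0] * 20 + [1] * 20)
    return X, y
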