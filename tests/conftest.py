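import numpy as np
import pytest

from spoilfuse.dataset_io import MultiModalDataset, SpectralBlock
from spoilfuse.synthetic_data import simulate_dataset, small_config


def make_block(matrix, modality="FTIR", axis=None, ids=None):
    matrix = np.asarray(matrix, dtype=float)
    n, p = matrix.shape
    if axis is None:
        axis = [1000.0 + i for i in range(p)]
    if ids is None:
        ids = [f"s{i}" for i in range(n)]
    return SpectralBlock(modality=modality, feature_axis=axis, matrix=matrix, sample_ids=ids)


@pytest.fixture(scope="session")
def small_dataset() -> MultiModalDataset:
    """A reduced two-batch, two-condition synthetic study (~130 samples)."""
    return simulate_dataset(small_config(seed=42))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)
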