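import numpy as np
import pytest

from figr.model import GeneCircuit
from figr.synthetic import gap_gene_like_circuit, sample_spatial_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def two_gene_circuit():
    """A two-gene circuit with mutual interactions and a spiral-type flow.

    Gene A activates B, B represses A; both hyperplanes cut through the
    bounding hypercube so trajectories cross them repeatedly.
    """
    return GeneCircuit(
        T=np.array([[0.4, -1.0], [1.0, 0.3]]),
        h=np.array([0.35, -0.45]),
        R=np.array([1.2, 1.0]),
        lam=np.array([1.0, 0.8]),
        genes=("A", "B"),
    )


@pytest.fixture(scope="session")
def spatial_truth():
    return gap_gene_like_circuit()


@pytest.fixture(scope="session")
def spatial_data(spatial_truth):
    """Noise-free spatiotemporal dataset from the patterning fixture:
    50 nuclei, initial slice + 8 time classes, 4 dynamic + 2 upstream genes."""
    return sample_spatial_dataset(spatial_truth)
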