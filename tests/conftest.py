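import numpy as np
import pytest

from hiermeta import HierarchyShape, connection_probabilities, sample_network
from hiermeta.dynamics import DynamicsConfig
from hiermeta.netgen import HierarchicalNetwork, build_partition


@pytest.fixture
def small_shape():
    return HierarchyShape(4, 2, 2)  # N = 16


@pytest.fixture
def study_shape():
    return HierarchyShape(16, 8, 2)  # N = 256, the study system


@pytest.fixture
def small_network(small_shape):
    probs = connection_probabilities(0.4, small_shape, k_target=5.0)
    return sample_network(probs, build_partition(small_shape), small_shape, seed=11)


@pytest.fixture
def quick_config():
    return DynamicsConfig(total_steps=2000, relax_steps=500, record_stride=10, seed=3)


def network_from_adjacency(A, partition) -> HierarchicalNetwork:
    """Wrap an explicit adjacency/partition pair (for closed-form fixtures)."""
    return HierarchicalNetwork(
        adjacency=np.asarray(A, dtype=np.uint8), partition=np.asarray(partition)
    )


def two_cliques(n: int):
    """Two disjoint K_n cliques; layer-1/2 partitions both split them apart."""
    N = 2 * n
    A = np.zeros((N, N), dtype=np.uint8)
    A[:n, :n] = 1
    A[n:, n:] = 1
    np.fill_diagonal(A, 0)
    labels = np.repeat([1, 2], n)
    P = np.vstack([labels, labels, np.ones(N, dtype=int)])
    return network_from_adjacency(A, P)
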