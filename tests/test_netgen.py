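import numpy as np
import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st
from scipy.sparse.csgraph import connected_components

from hiermeta import (
    HierarchyShape,
    build_partition,
    configuration_model_control,
    connection_probabilities,
    gamma_for_degree,
    modularity,
    rewire,
    sample_network,
    theoretical_mean_degree,
)
from hiermeta.netgen import (
    InvalidShapeError,
    ParameterizationError,
    RewireError,
    pair_probability_matrix,
)

from conftest import network_from_adjacency, two_cliques


@pytest.mark.parametrize(
    "n1,n2,n3",
    [(2, 4, 2), (16, 8, 2), (4, 2, 2), (3, 1, 1), (5, 3, 2)],
)
def test_partition_nesting_and_contiguity(n1, n2, n3):
    shape = HierarchyShape(n1, n2, n3)
    P = build_partition(shape)
    assert P.shape == (3, shape.N)
    # single top block
    assert np.all(P[2] == 1)
    # block counts per layer
    assert np.unique(P[0]).size == shape.B1
    assert np.unique(P[1]).size == shape.B2
    # nesting: same block at layer l implies same block at all layers above
    for lower, upper in [(0, 1), (1, 2)]:
        for b in np.unique(P[lower]):
            assert np.unique(P[upper][P[lower] == b]).size == 1
    # block-contiguous ordering and exact block sizes prod(n_j, j<=l)
    for l, size in [(0, n1), (1, n1 * n2), (2, shape.N)]:
        for b in np.unique(P[l]):
            idx = np.flatnonzero(P[l] == b)
            assert idx.size == size
            assert np.array_equal(idx, np.arange(idx[0], idx[0] + size))


def test_partition_example_counts():
    P = build_partition(HierarchyShape(2, 4, 2))
    assert P.shape[1] == 16
    assert [np.unique(P[l]).size for l in range(3)] == [8, 2, 1]


@pytest.mark.parametrize("bad", [0, -3, 2.5, True])
def test_invalid_shape_rejected(bad):
    with pytest.raises(InvalidShapeError):
        HierarchyShape(bad, 2, 2)


def test_gamma_for_degree_bounds_and_inversion():
    shape = HierarchyShape(16, 8, 2)
    assert gamma_for_degree(shape, 15.0) == 0.0
    assert gamma_for_degree(shape, 127.0) == 1.0
    assert np.isclose(gamma_for_degree(shape, 51.2), 36.2 / 112)  # ~0.3232
    with pytest.raises(ParameterizationError, match="14.*126|15.*127"):
        gamma_for_degree(shape, 10.0)
    with pytest.raises(ParameterizationError):
        gamma_for_degree(shape, 200.0)


def test_connection_probability_limits():
    shape = HierarchyShape(16, 8, 2)
    pr = connection_probabilities(1.0, shape, k_target=51.2)
    assert pr.p3 == 0.0  # decoupled populations
    pr0 = connection_probabilities(0.0, shape, k_target=51.2)
    assert pr0.p2 == pytest.approx(pr0.p3)  # reduces to a flat 2-level SBM
    assert pr0.p2 == pytest.approx(pr0.gamma / 2)
    pr5 = connection_probabilities(0.5, shape, k_target=51.2)
    gamma = 36.2 / 112
    assert pr5.p2 == pytest.approx(0.75 * gamma)   # ~0.2424
    assert pr5.p3 == pytest.approx(0.25 * gamma)   # ~0.0808
    with pytest.raises(ParameterizationError):
        connection_probabilities(1.2, shape, k_target=51.2)
    with pytest.raises(ParameterizationError):
        connection_probabilities(0.5, shape, gamma=1.4)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    H=st.floats(0, 1),
    n1=st.integers(2, 20),
    n2=st.integers(2, 10),
    frac=st.floats(0, 1),
)
def test_mean_degree_conserved_and_probability_order(H, n1, n2, frac):
    """The closed-form mean degree equals the target for every H (conservation),
    and probabilities are ordered densest-first for the admissible densities."""
    shape = HierarchyShape(n1, n2, 2)
    lo, hi = n1 - 1.0, n1 * n2 - 1.0
    k = lo + frac * (hi - lo)
    probs = connection_probabilities(H, shape, k_target=k)
    assert theoretical_mean_degree(probs, shape) == pytest.approx(k, abs=1e-9)
    if probs.gamma <= 2 * (n1 - 1) / (2 * n1 - 1):
        assert probs.p1 >= probs.p2 - 1e-12 >= probs.p3 - 1e-12


def test_mean_degree_H_independent_to_machine_precision():
    shape = HierarchyShape(16, 8, 2)
    vals = [
        theoretical_mean_degree(connection_probabilities(H, shape, k_target=51.2), shape)
        for H in np.arange(0, 1.01, 0.1)
    ]
    assert np.ptp(vals) < 1e-12


def test_mean_degree_matches_per_pair_summation_oracle():
    """Independent oracle: sum all pair probabilities directly and divide by N."""
    shape = HierarchyShape(4, 3, 2)
    probs = connection_probabilities(0.37, shape, k_target=6.5)
    M = pair_probability_matrix(probs, build_partition(shape))
    assert M.sum() / shape.N == pytest.approx(
        theoretical_mean_degree(probs, shape), abs=1e-9
    )
    assert theoretical_mean_degree(
        connection_probabilities(0.3, shape, gamma=0.0), shape
    ) == pytest.approx(shape.n1 - 1)


def test_sampled_network_is_simple_and_reproducible(study_shape):
    probs = connection_probabilities(0.5, study_shape, k_target=51.2)
    P = build_partition(study_shape)
    net = sample_network(probs, P, study_shape, seed=5)
    A = net.adjacency
    assert np.array_equal(A, A.T)
    assert np.all(np.diag(A) == 0)
    assert set(np.unique(A)) <= {0, 1}
    assert np.array_equal(A, sample_network(probs, P, study_shape, seed=5).adjacency)
    assert not np.array_equal(A, sample_network(probs, P, study_shape, seed=6).adjacency)


def test_decoupled_sampling_splits_into_populations(study_shape):
    probs = connection_probabilities(1.0, study_shape, k_target=51.2)
    P = build_partition(study_shape)
    net = sample_network(probs, P, study_shape, seed=1)
    ncomp, labels = connected_components(net.to_csr(), directed=False)
    assert ncomp == 2
    for pop in (1, 2):
        assert np.unique(labels[P[1] == pop]).size == 1


def test_sampled_mean_degree_within_three_standard_errors(study_shape):
    probs = connection_probabilities(0.7, study_shape, k_target=51.2)
    P = build_partition(study_shape)
    M = pair_probability_matrix(probs, P)
    var_edges = (M * (1 - M))[np.triu_indices(study_shape.N, k=1)].sum()
    se = 2 * np.sqrt(var_edges) / study_shape.N
    degs = [
        sample_network(probs, P, study_shape, seed=s).mean_degree for s in range(3)
    ]
    assert abs(np.mean(degs) - 51.2) < 3 * se / np.sqrt(3)


def test_per_pair_frequencies_match_block_probabilities():
    """Brute-force oracle: empirical connection frequency of every node pair over
    a resampled ensemble matches p1/p2/p3 within 3 binomial standard errors."""
    shape = HierarchyShape(2, 2, 2)  # N = 8
    probs = connection_probabilities(0.6, shape, k_target=2.0)
    P = build_partition(shape)
    n_rep = 2000
    counts = np.zeros((shape.N, shape.N))
    for s in range(n_rep):
        counts += sample_network(probs, P, shape, seed=s).adjacency
    freq = counts / n_rep
    M = pair_probability_matrix(probs, P)
    se = np.sqrt(np.maximum(M * (1 - M), 1e-12) / n_rep)
    iu = np.triu_indices(shape.N, k=1)
    assert np.all(np.abs(freq[iu] - M[iu]) <= 3 * se[iu] + 1e-9)


def test_layer_homogeneity_of_degrees(study_shape):
    probs = connection_probabilities(0.5, study_shape, k_target=51.2)
    P = build_partition(study_shape)
    net = sample_network(probs, P, study_shape, seed=9)
    block_means = [net.degrees[P[0] == b].mean() for b in np.unique(P[0])]
    # per-module mean degree fluctuates by ~sd/sqrt(n1) around the common mean
    assert np.std(block_means) < 3 * net.degrees.std() / np.sqrt(study_shape.n1)


def test_modularity_closed_forms():
    cliques = two_cliques(5)
    assert modularity(cliques, 2) == pytest.approx(0.5)
    N = 8
    A = np.ones((N, N), dtype=np.uint8)
    np.fill_diagonal(A, 0)
    P = np.vstack([np.ones(N, int)] * 3)
    assert modularity(network_from_adjacency(A, P), 1) == pytest.approx(0.0)
    empty = network_from_adjacency(np.zeros((4, 4)), np.ones((3, 4), int))
    with pytest.raises(ValueError):
        modularity(empty, 1)


def test_modularity_agrees_with_networkx(small_network):
    """Dual route: our vectorized Newman Q against the networkx implementation."""
    G = nx.from_numpy_array(small_network.adjacency)
    for layer in (1, 2):
        labels = small_network.partition[layer - 1]
        comms = [set(np.flatnonzero(labels == b)) for b in np.unique(labels)]
        assert modularity(small_network, layer) == pytest.approx(
            nx.community.modularity(G, comms), abs=1e-12
        )


def test_population_modularity_increases_with_H(study_shape):
    P = build_partition(study_shape)
    means = []
    for H in (0.1, 0.5, 0.9):
        probs = connection_probabilities(H, study_shape, k_target=51.2)
        means.append(
            np.mean(
                [
                    modularity(sample_network(probs, P, study_shape, seed=s), 2)
                    for s in range(3)
                ]
            )
        )
    assert means[0] < means[1] < means[2]


def test_rewire_conserves_edges_and_simplicity(small_network):
    same = rewire(small_network, 0, seed=1)
    assert np.array_equal(same.adjacency, small_network.adjacency)
    moved = rewire(small_network, 200, seed=1)
    assert moved.n_edges == small_network.n_edges
    A = moved.adjacency
    assert np.array_equal(A, A.T) and np.all(np.diag(A) == 0)
    assert set(np.unique(A)) <= {0, 1}
    swapped = rewire(small_network, 200, seed=1, degree_preserving=True)
    assert np.array_equal(np.sort(swapped.degrees), np.sort(small_network.degrees))


def test_rewire_dense_graph_has_no_target():
    N = 5
    A = np.ones((N, N), dtype=np.uint8)
    np.fill_diagonal(A, 0)
    net = network_from_adjacency(A, np.ones((3, N), int))
    with pytest.raises(RewireError):
        rewire(net, 1, seed=0, max_attempts=50)


def test_heavy_rewiring_destroys_modularity(study_shape):
    probs = connection_probabilities(0.5, study_shape, k_target=51.2)
    P = build_partition(study_shape)
    net = sample_network(probs, P, study_shape, seed=2)
    assert modularity(net, 2) > 0.2
    q2_before = modularity(net, 2)
    randomized = rewire(net, 10_000, seed=3)
    # mesoscale structure is essentially gone: Q at the random-graph
    # fluctuation scale and an order of magnitude below the original
    assert abs(modularity(randomized, 2)) < 0.06
    assert abs(modularity(randomized, 1)) < 0.06
    assert abs(modularity(randomized, 2)) < 0.2 * q2_before


def test_configuration_model_uniform_degree():
    P = build_partition(HierarchyShape(4, 2, 2))
    net = configuration_model_control(16, 6, P, seed=0)
    assert np.all(net.degrees == 6)
    assert np.array_equal(net.partition, P)
    Pp = build_partition(HierarchyShape(16, 8, 2))
    ctrl = configuration_model_control(256, 51, Pp, seed=1)  # 256*51 is even
    assert np.all(ctrl.degrees == 51)
    assert abs(modularity(ctrl, 2)) < 0.05
    with pytest.raises(ValueError, match="handshake"):
        configuration_model_control(5, 3, np.ones((3, 5), int), seed=0)
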