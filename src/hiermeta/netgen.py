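"""Single-parameter nested stochastic block model (nSBM) with conserved mean degree.

The generator builds 3-layer hierarchically modular, unweighted, undirected
graphs.  Layer-1 blocks ("modules") are grouped into layer-2 blocks
("populations"), which form a single layer-3 block (the whole system, modelling
the two-hemisphere division when ``n3 = 2``).  A single structural parameter
``H`` interpolates from a flat two-level SBM (H=0, the two populations are
statistically indistinguishable from one) to two fully decoupled populations
(H=1), while the expected mean degree ``<k>`` is held exactly constant.

Connection probabilities (deepest shared block decides which applies)::

    p1(H) = 1 - (1-H)/2 * n1*gamma/(n1-1)     same module
    p2(H) = (1+H)/2 * gamma                   same population, different module
    p3(H) = (1-H)/2 * gamma                   different population

with the density factor ``gamma`` in [0, 1] chosen so that

    <k> = (n1-1)*p1 + n1*(n2-1)*p2 + n1*n2*(n3-1)*p3 = (n1-1) + gamma*n1*(n2-1)

matches a target mean degree, which is therefore admissible in
``[n1-1, n1*n2-1]`` and independent of ``H``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import networkx as nx
import numpy as np
import scipy.sparse as sp

__all__ = [
    "HierarchyShape",
    "PartitionMatrix",
    "ConnectionProbabilities",
    "HierarchicalNetwork",
    "InvalidShapeError",
    "ParameterizationError",
    "RewireError",
    "build_partition",
    "gamma_for_degree",
    "connection_probabilities",
    "theoretical_mean_degree",
    "pair_probability_matrix",
    "sample_network",
    "modularity",
    "rewire",
    "configuration_model_control",
]

PartitionMatrix = np.ndarray  # (L, N) int array, 1-based block ids per layer


class InvalidShapeError(ValueError):
    """Raised for non-integer or non-positive layer sizes."""


class ParameterizationError(ValueError):
    """Raised when (H, gamma) yield an out-of-range connection probability."""


class RewireError(RuntimeError):
    """Raised when no admissible rewiring target can be found."""


@dataclass(frozen=True)
class HierarchyShape:
    """Layer sizes of the 3-layer hierarchy.

    ``n1`` nodes per module, ``n2`` modules per population, ``n3`` populations.
    Derived counts: ``B1 = n2*n3`` modules, ``B2 = n3`` populations, ``B3 = 1``.
    """

    n1: int
    n2: int
    n3: int = 2

    def __post_init__(self) -> None:
        for name in ("n1", "n2", "n3"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool) or v < 1:
                raise InvalidShapeError(f"{name} must be a positive integer, got {v!r}")

    @property
    def N(self) -> int:
        return self.n1 * self.n2 * self.n3

    @property
    def B1(self) -> int:
        return self.n2 * self.n3

    @property
    def B2(self) -> int:
        return self.n3

    @property
    def B3(self) -> int:
        return 1

    def block_count(self, layer: int) -> int:
        return {1: self.B1, 2: self.B2, 3: self.B3}[layer]

    def block_size(self, layer: int) -> int:
        """Number of nodes in a single layer-``layer`` block."""
        return {1: self.n1, 2: self.n1 * self.n2, 3: self.N}[layer]


@dataclass(frozen=True)
class ConnectionProbabilities:
    """Per-pair connection probabilities of the nSBM at a given (H, gamma)."""

    H: float
    gamma: float
    p1: float
    p2: float
    p3: float
    k_target: Optional[float] = None


@dataclass
class HierarchicalNetwork:
    """An undirected simple graph together with its hierarchical partition.

    ``adjacency`` is a dense symmetric 0/1 uint8 matrix with zero diagonal.
    ``shape`` / ``probs`` are absent for user-supplied or control networks.
    """

    adjacency: np.ndarray
    partition: PartitionMatrix
    shape: Optional[HierarchyShape] = None
    probs: Optional[ConnectionProbabilities] = None
    seed: Optional[int] = None

    @property
    def N(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(np.int64)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def mean_degree(self) -> float:
        return 2.0 * self.n_edges / self.N

    def block_count(self, layer: int) -> int:
        return int(np.unique(self.partition[layer - 1]).size)

    def nodes_in_block(self, layer: int, block: int) -> np.ndarray:
        return np.flatnonzero(self.partition[layer - 1] == block)

    def to_csr(self) -> sp.csr_matrix:
        return sp.csr_matrix(self.adjacency)

    def copy(self) -> "HierarchicalNetwork":
        return HierarchicalNetwork(
            adjacency=self.adjacency.copy(),
            partition=self.partition.copy(),
            shape=self.shape,
            probs=self.probs,
            seed=self.seed,
        )


def build_partition(shape: HierarchyShape) -> PartitionMatrix:
    """Return the (3, N) partition matrix with block-contiguous node ordering.

    Row ``l-1`` assigns every node its 1-based layer-``l`` block id.  Nodes of
    module 1 come first, then module 2, etc., so adjacency matrices render with
    the nested block structure on the diagonal and partition slices are index
    ranges.
    """
    n1, n2, n3 = shape.n1, shape.n2, shape.n3
    idx = np.arange(shape.N)
    P = np.vstack(
        [
            idx // n1 + 1,
            idx // (n1 * n2) + 1,
            np.ones(shape.N, dtype=np.int64),
        ]
    ).astype(np.int64)
    return P


def gamma_for_degree(shape: HierarchyShape, k_target: float) -> float:
    """Invert the closed-form mean degree for the density factor gamma.

    ``<k> = (n1-1) + gamma*n1*(n2-1)`` so the admissible range of ``k_target``
    is ``[n1-1, n1*n2-1]`` (isolated near-cliques up to one merged population).
    """
    n1, n2 = shape.n1, shape.n2
    lo, hi = n1 - 1.0, n1 * n2 - 1.0
    if not (lo <= k_target <= hi):
        raise ParameterizationError(
            f"k_target={k_target} outside admissible range [{lo}, {hi}] "
            f"for n1={n1}, n2={n2}"
        )
    if hi == lo:
        return 0.0
    return (k_target - lo) / (n1 * (n2 - 1.0))


def connection_probabilities(
    H: float,
    shape: HierarchyShape,
    k_target: Optional[float] = None,
    gamma: Optional[float] = None,
) -> ConnectionProbabilities:
    """Evaluate p1, p2, p3 at structural parameter ``H``.

    Exactly one of ``k_target`` or ``gamma`` must be given.  Raises
    :class:`ParameterizationError` rather than clipping if ``p1`` leaves
    [0, 1], since clipping would silently break degree conservation.
    """
    if not (0.0 <= H <= 1.0):
        raise ParameterizationError(f"H must be in [0, 1], got {H}")
    if (k_target is None) == (gamma is None):
        raise ValueError("specify exactly one of k_target or gamma")
    if gamma is None:
        gamma = gamma_for_degree(shape, k_target)
    if not (0.0 <= gamma <= 1.0):
        raise ParameterizationError(f"gamma must be in [0, 1], got {gamma}")
    n1 = shape.n1
    p1 = 1.0 - (1.0 - H) / 2.0 * n1 * gamma / (n1 - 1.0) if n1 > 1 else 1.0
    p2 = (1.0 + H) / 2.0 * gamma
    p3 = (1.0 - H) / 2.0 * gamma
    for name, p in (("p1", p1), ("p2", p2), ("p3", p3)):
        if not (-1e-12 <= p <= 1.0 + 1e-12):
            raise ParameterizationError(
                f"{name}={p} outside [0, 1] for H={H}, gamma={gamma}"
            )
    return ConnectionProbabilities(
        H=float(H), gamma=float(gamma), p1=float(np.clip(p1, 0.0, 1.0)),
        p2=float(np.clip(p2, 0.0, 1.0)), p3=float(np.clip(p3, 0.0, 1.0)),
        k_target=None if k_target is None else float(k_target),
    )


def theoretical_mean_degree(
    probs: ConnectionProbabilities, shape: HierarchyShape
) -> float:
    """Expected degree of every node: the sum of one row of pair probabilities."""
    n1, n2, n3 = shape.n1, shape.n2, shape.n3
    return (
        (n1 - 1) * probs.p1
        + n1 * (n2 - 1) * probs.p2
        + n1 * n2 * (n3 - 1) * probs.p3
    )


def pair_probability_matrix(
    probs: ConnectionProbabilities, partition: PartitionMatrix
) -> np.ndarray:
    """Dense (N, N) matrix of per-pair connection probabilities, zero diagonal."""
    same1 = partition[0][:, None] == partition[0][None, :]
    same2 = partition[1][:, None] == partition[1][None, :]
    M = np.where(same1, probs.p1, np.where(same2, probs.p2, probs.p3))
    np.fill_diagonal(M, 0.0)
    return M


def sample_network(
    probs: ConnectionProbabilities,
    partition: PartitionMatrix,
    shape: HierarchyShape,
    seed,
) -> HierarchicalNetwork:
    """Draw one network: independent Bernoulli per unordered pair (standard SBM)."""
    rng = np.random.default_rng(seed)
    N = shape.N
    M = pair_probability_matrix(probs, partition)
    U = rng.random((N, N))
    upper = np.triu(U < M, k=1)
    A = (upper | upper.T).astype(np.uint8)
    return HierarchicalNetwork(
        adjacency=A,
        partition=partition,
        shape=shape,
        probs=probs,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
    )


def modularity(network: HierarchicalNetwork, layer: int) -> float:
    """Newman modularity Q of the layer-``layer`` partition.

    Q = sum_c [ e_c/m - (deg_c / 2m)^2 ]  with e_c the intra-community edge
    count, deg_c the community degree sum and m the total edge count.
    """
    m = network.n_edges
    if m == 0:
        raise ValueError("modularity undefined for an empty edge set")
    labels = network.partition[layer - 1]
    A = network.adjacency
    deg = network.degrees
    Q = 0.0
    for c in np.unique(labels):
        mask = labels == c
        e_c = A[np.ix_(mask, mask)].sum() / 2.0
        deg_c = deg[mask].sum()
        Q += e_c / m - (deg_c / (2.0 * m)) ** 2
    return float(Q)


def rewire(
    network: HierarchicalNetwork,
    r: int,
    seed,
    degree_preserving: bool = False,
    max_attempts: int = 1000,
) -> HierarchicalNetwork:
    """Apply exactly ``r`` random rewiring moves, conserving the edge count.

    Default move: pick a random edge (u, v), keep one uniformly chosen
    endpoint, reattach the edge to a uniformly chosen node that is not already
    adjacent to the kept endpoint and differs from both endpoints.  Conserves
    |E| but not the degree sequence.  With ``degree_preserving=True`` a
    double-edge swap is used instead (two edges exchange endpoints), which
    conserves every node's degree.
    """
    if r < 0:
        raise ValueError("r must be >= 0")
    rng = np.random.default_rng(seed)
    out = network.copy()
    A = out.adjacency
    N = out.N
    edges = np.argwhere(np.triu(A, k=1))
    edges = [tuple(e) for e in edges]
    for _ in range(int(r)):
        for _attempt in range(max_attempts):
            ei = int(rng.integers(len(edges)))
            u, v = edges[ei]
            if degree_preserving:
                ej = int(rng.integers(len(edges)))
                x, y = edges[ej]
                if rng.random() < 0.5:
                    x, y = y, x
                # swap (u,v),(x,y) -> (u,x),(v,y)
                if len({u, v, x, y}) == 4 and not A[u, x] and not A[v, y]:
                    A[u, v] = A[v, u] = 0
                    A[x, y] = A[y, x] = 0
                    A[u, x] = A[x, u] = 1
                    A[v, y] = A[y, v] = 1
                    edges[ei] = (min(u, x), max(u, x))
                    edges[ej] = (min(v, y), max(v, y))
                    break
            else:
                keep, drop = (u, v) if rng.random() < 0.5 else (v, u)
                t = int(rng.integers(N))
                if t != u and t != v and not A[keep, t]:
                    A[u, v] = A[v, u] = 0
                    A[keep, t] = A[t, keep] = 1
                    edges[ei] = (min(keep, t), max(keep, t))
                    break
        else:
            raise RewireError(
                f"no admissible rewiring target found in {max_attempts} attempts"
            )
    out.probs = None
    return out


def configuration_model_control(
    N: int, k: int, partition: PartitionMatrix, seed
) -> HierarchicalNetwork:
    """k-regular random control network carrying ``partition`` for lag assignment.

    Every node has degree exactly ``k`` (uniform degree sequence; stub matchings
    with self-loops or multi-edges are resampled).  Requires ``N*k`` even by the
    handshake lemma.
    """
    if (N * k) % 2 != 0:
        raise ValueError(
            f"unsatisfiable degree sequence: N*k = {N}*{k} is odd (handshake lemma)"
        )
    if not (0 <= k < N):
        raise ValueError(f"need 0 <= k < N, got k={k}, N={N}")
    if isinstance(seed, (int, np.integer)):
        nx_seed = int(seed)
    else:  # SeedSequence / Generator: derive a 32-bit int for networkx
        nx_seed = int(np.random.default_rng(seed).integers(2**31))
    G = nx.random_regular_graph(k, N, seed=nx_seed)
    A = nx.to_numpy_array(G, nodelist=range(N), dtype=np.uint8)
    return HierarchicalNetwork(adjacency=A, partition=np.asarray(partition))
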