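"""Graph-Laplacian spectrum, spectral gaps and Laplacian renormalization group.

The Laplacian L = D - A of the hierarchical networks has eigenvalues
0 = lambda_1 <= ... <= lambda_N whose inverses act as mode timescales.  Two
gaps organize the dynamics: gap1 = lambda_{B2+1} - lambda_{B2} separates the
slowest (whole-system) mode from the population modes, and
gap2 = lambda_{B1+1} - lambda_{B1} separates the slow modes carrying layer-2
structure from the fast intra-module modes.

The LRG coarse-graining truncates the spectral resolution of L at
lambda* (default lambda_{B1+1}), keeping the B1 slow modes, and projects the
rescaled Laplacian onto the layer-1 block indicator vectors to obtain an
effective weighted B1 x B1 network A' comparable to the two-population model.
Its symmetry-breaking parameter a' = (K1 - K2)/(K1 + K2) compares mean
intra-population (K1) and inter-population (K2) block couplings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import scipy.linalg

from .netgen import HierarchicalNetwork

__all__ = [
    "SpectralProfile",
    "CoarseGrainedNetwork",
    "laplacian",
    "spectrum",
    "lrg_rescale",
    "coarse_grain",
    "symmetry_breaking",
    "coarse_grained_network",
    "a_prime",
    "gap_metastability_cutoff",
]

_TIE_TOL = 1e-9


@dataclass
class SpectralProfile:
    """Sorted eigensystem of a graph Laplacian plus the two layer gaps."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    B1: int
    B2: int

    @property
    def gap1(self) -> float:
        return float(self.eigenvalues[self.B2] - self.eigenvalues[self.B2 - 1])

    @property
    def gap2(self) -> float:
        return float(self.eigenvalues[self.B1] - self.eigenvalues[self.B1 - 1])


@dataclass
class CoarseGrainedNetwork:
    """LRG coarse-grained weighted network with population coupling summary."""

    A_prime: np.ndarray
    lambda_star: float
    K1: float
    K2: float
    a_prime: float


def laplacian(network: HierarchicalNetwork) -> np.ndarray:
    """Combinatorial Laplacian L = D - A (dense, float)."""
    A = network.adjacency.astype(float)
    return np.diag(A.sum(axis=1)) - A


def spectrum(
    L: np.ndarray, B1: Optional[int] = None, B2: Optional[int] = None
) -> SpectralProfile:
    """Full sorted eigendecomposition of a symmetric Laplacian."""
    L = np.asarray(L, dtype=float)
    if not np.allclose(L, L.T, atol=1e-10):
        raise ValueError("Laplacian must be symmetric")
    evals, evecs = scipy.linalg.eigh(L)
    n = L.shape[0]
    if B1 is None:
        B1 = min(16, n - 1)
    if B2 is None:
        B2 = min(2, n - 1)
    return SpectralProfile(eigenvalues=evals, eigenvectors=evecs, B1=B1, B2=B2)


def spectrum_of(network: HierarchicalNetwork) -> SpectralProfile:
    """Convenience: spectrum of a hierarchical network with its own B1, B2."""
    B1 = network.shape.B1 if network.shape is not None else network.block_count(1)
    B2 = network.shape.B2 if network.shape is not None else network.block_count(2)
    return spectrum(laplacian(network), B1=B1, B2=B2)


def lrg_rescale(
    profile: SpectralProfile,
    lambda_star: Optional[float] = None,
    modes: str = "slow",
) -> np.ndarray:
    """Time-rescaled Laplacian L' = sum_{lambda_i < lambda*} lambda_i |i><i|.

    Defaults to lambda* = lambda_{B1+1}, i.e. the B1 slowest modes are kept
    (index-based when the truncation boundary is degenerate to 1e-9).  With
    ``modes="fast"`` the complementary sum over the discarded fast modes is
    returned instead; coarse-graining that complement reconstructs the
    short-timescale connectivity (see the methods note for when each view is
    informative).
    """
    if modes not in ("slow", "fast"):
        raise ValueError("modes must be 'slow' or 'fast'")
    evals, evecs = profile.eigenvalues, profile.eigenvectors
    if lambda_star is None:
        lstar = float(evals[profile.B1])
        if abs(evals[profile.B1] - evals[profile.B1 - 1]) < _TIE_TOL:
            keep = np.arange(profile.B1)  # degenerate boundary: keep B1 by index
        else:
            keep = np.flatnonzero(evals < lstar)
    else:
        lstar = float(lambda_star)
        if lstar <= 0:
            raise ValueError("lambda_star must be positive")
        keep = np.flatnonzero(evals < lstar)
    if modes == "fast":
        keep = np.setdiff1d(np.arange(evals.size), keep)
    V = evecs[:, keep]
    return (V * evals[keep]) @ V.T


def coarse_grain(
    L_prime: np.ndarray, partition: np.ndarray, layer: int = 1
) -> np.ndarray:
    """Project L' onto unnormalized 0/1 block indicators: A'_ab = -<a|L'|b>.

    The diagonal is zeroed (no self interactions) and the result symmetrized
    against floating-point asymmetry.  At lambda* = infinity (L' = L) the
    off-diagonal entries are exactly the inter-block edge counts.
    """
    labels = np.asarray(partition)[layer - 1]
    blocks = np.unique(labels)
    N = labels.size
    if np.asarray(L_prime).shape != (N, N):
        raise ValueError("partition and L' dimensions disagree")
    C = (labels[:, None] == blocks[None, :]).astype(float)  # (N, B)
    Ap = -(C.T @ L_prime @ C)
    np.fill_diagonal(Ap, 0.0)
    return (Ap + Ap.T) / 2.0


def symmetry_breaking(
    A_prime: np.ndarray, block_population: np.ndarray
) -> Tuple[float, float, float]:
    """(K1, K2, a') of a coarse-grained network.

    K1: mean off-diagonal coupling between blocks of the same population;
    K2: mean coupling between blocks of different populations;
    a' = (K1 - K2)/(K1 + K2), invariant under uniform scaling of A'.
    """
    Ap = np.asarray(A_prime, dtype=float)
    pop = np.asarray(block_population)
    B = Ap.shape[0]
    if pop.size != B:
        raise ValueError("block population labels must match A' dimension")
    if np.unique(pop).size != 2:
        raise ValueError("symmetry breaking requires exactly 2 populations")
    same = pop[:, None] == pop[None, :]
    off = ~np.eye(B, dtype=bool)
    K1 = float(Ap[same & off].mean())
    K2 = float(Ap[~same].mean())
    if K1 + K2 == 0:
        raise ZeroDivisionError("a' undefined: K1 + K2 = 0")
    return K1, K2, (K1 - K2) / (K1 + K2)


def _block_population(network: HierarchicalNetwork) -> np.ndarray:
    labels1 = network.partition[0]
    blocks = np.unique(labels1)
    return np.array(
        [network.partition[1][labels1 == b][0] for b in blocks], dtype=np.int64
    )


def coarse_grained_network(
    network: HierarchicalNetwork,
    lambda_star: Optional[float] = None,
    modes: str = "slow",
) -> CoarseGrainedNetwork:
    """Full LRG pipeline: spectrum -> L' -> A' -> (K1, K2, a')."""
    profile = spectrum_of(network)
    lstar = (
        float(profile.eigenvalues[profile.B1]) if lambda_star is None else lambda_star
    )
    Lp = lrg_rescale(profile, lambda_star, modes=modes)
    Ap = coarse_grain(Lp, network.partition, layer=1)
    K1, K2, ap = symmetry_breaking(Ap, _block_population(network))
    return CoarseGrainedNetwork(A_prime=Ap, lambda_star=lstar, K1=K1, K2=K2, a_prime=ap)


def a_prime(
    network: HierarchicalNetwork,
    lambda_star: Optional[float] = None,
    modes: str = "slow",
) -> float:
    return coarse_grained_network(network, lambda_star, modes=modes).a_prime


def gap_metastability_cutoff(
    gaps: np.ndarray, sigma_met1: np.ndarray
) -> Optional[float]:
    """Gap value at which sigma_met^1 collapses off its small-gap plateau.

    ``gaps`` and ``sigma_met1`` are paired sweep points (any order).  On the
    log-log curve of sigma versus gap, the plateau level is the mean sigma of
    the two smallest-gap points and the floor level the mean of the two
    largest-gap points; the cutoff is where the piecewise-linear log-log curve
    crosses the half-way (geometric-midpoint) level between the two.  Located
    between the last point at or above that level (in increasing gap) and its
    successor.  Returns None when the curve never crosses (no cutoff in range).
    """
    gaps = np.asarray(gaps, dtype=float)
    sig = np.asarray(sigma_met1, dtype=float)
    if gaps.size != sig.size or gaps.size < 4:
        raise ValueError("need >= 4 paired sweep points")
    if np.any(gaps <= 0) or np.any(sig <= 0):
        raise ValueError("gaps and sigma values must be positive for log interpolation")
    order = np.argsort(gaps)
    gaps, sig = gaps[order], sig[order]
    plateau = sig[:2].mean()
    floor = sig[-2:].mean()
    level = np.sqrt(plateau * floor)
    above = np.flatnonzero(sig >= level)
    if above.size == 0 or above[-1] == gaps.size - 1:
        return None  # never collapses within the sweep
    i = int(above[-1])
    g1, g2 = np.log(gaps[i]), np.log(gaps[i + 1])
    s1, s2 = np.log(sig[i]), np.log(sig[i + 1])
    t = (s1 - np.log(level)) / (s1 - s2)
    return float(np.exp(g1 + t * (g2 - g1)))
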