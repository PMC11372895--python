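"""Frustrated Kuramoto-Sakaguchi dynamics on hierarchical networks.

Equation of motion (attractive convention)::

    dtheta_i/dt = omega_i + K * sum_j A_ij sin(theta_j - theta_i - alpha_ij)

with a layer-dependent phase lag: alpha_ij = 0 when i and j share a layer-1
module, alpha_ij = alpha = pi/2 - beta otherwise.  Oscillators are identical
(omega_i = 1) unless a frequency spread ``omega_sd`` is requested, and the
coupling K = K_numerator/<k> is normalized by the target mean degree so that
networks of different density are comparable.

Integration is explicit Euler with the default step dt = 0.001 over 55,000
steps, the first 5,000 of which are discarded as relaxation by all downstream
statistics.  A dense pure-numpy integrator (`reference_simulate`) implementing
the per-pair lag matrix definition directly is kept as an independent
cross-check of the accelerated kernel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import scipy.sparse as sp

from ._kernels import euler_ks
from .netgen import HierarchicalNetwork

__all__ = [
    "DynamicsConfig",
    "PhaseTrajectory",
    "IntegrationDivergedError",
    "lag_for_pair",
    "sample_frequencies",
    "simulate",
    "reference_simulate",
]


class IntegrationDivergedError(RuntimeError):
    """Raised when a non-finite phase is produced during integration."""


@dataclass(frozen=True)
class DynamicsConfig:
    """Integration settings.

    beta: lag parameter in radians; the Sakaguchi lag applied to inter-module
        pairs is alpha = pi/2 - beta, so beta -> 0 is maximal frustration.
    K_numerator: coupling scale; effective K = K_numerator / <k>.
    record_stride: phases are stored every ``record_stride`` states (order
        parameters are always accumulated at every step).
    """

    beta: float = 0.1
    K_numerator: float = 50.0
    dt: float = 0.001
    total_steps: int = 55_000
    relax_steps: int = 5_000
    omega_mean: float = 1.0
    omega_sd: float = 0.0
    seed: int = 0
    record_stride: int = 50

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not (0 <= self.relax_steps < self.total_steps):
            raise ValueError("need 0 <= relax_steps < total_steps")
        if not (-math.pi / 2 < self.beta <= math.pi / 2):
            raise ValueError("beta must lie in (-pi/2, pi/2]")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")
        if self.omega_sd < 0:
            raise ValueError("omega_sd must be >= 0")

    @property
    def alpha(self) -> float:
        return math.pi / 2 - self.beta


@dataclass
class PhaseTrajectory:
    """Result of one integration.

    theta: (n_rec, N) phases wrapped to (-pi, pi], recorded at states
        0, stride, 2*stride, ... < total_steps.
    times: corresponding time stamps (state index * dt).
    block_phasors: (total_steps, B1) complex per-module phasor sums at states
        1..total_steps; every order parameter derives exactly from these.
    module_sizes: (B1,) node counts per layer-1 module (partition order).
    module_population: (B1,) 1-based population id of each module.
    """

    theta: np.ndarray
    times: np.ndarray
    config: DynamicsConfig
    network: HierarchicalNetwork
    block_phasors: np.ndarray
    module_sizes: np.ndarray
    module_population: np.ndarray
    k_effective: float
    theta_final: np.ndarray


def lag_for_pair(partition: np.ndarray, u: int, v: int, beta: float) -> float:
    """Phase lag for the pair (u, v): 0 inside a module, pi/2 - beta across."""
    if u == v:
        raise ValueError("phase lag undefined for a self-pair")
    return 0.0 if partition[0][u] == partition[0][v] else math.pi / 2 - beta


def sample_frequencies(N: int, omega_mean: float, omega_sd: float, seed) -> np.ndarray:
    """Natural frequencies: exactly constant when omega_sd == 0, else N(mean, sd)."""
    if omega_sd < 0:
        raise ValueError("omega_sd must be >= 0")
    if omega_sd == 0:
        return np.full(N, float(omega_mean))
    rng = np.random.default_rng(seed)
    return rng.normal(omega_mean, omega_sd, size=N)


def _split_edges(network: HierarchicalNetwork):
    """CSR index arrays for intra-module (zero-lag) and inter-module edges."""
    A = network.adjacency
    same = network.partition[0][:, None] == network.partition[0][None, :]
    intra = sp.csr_matrix(np.where(same, A, 0))
    inter = sp.csr_matrix(np.where(same, 0, A))
    return (
        intra.indptr.astype(np.int64),
        intra.indices.astype(np.int64),
        inter.indptr.astype(np.int64),
        inter.indices.astype(np.int64),
    )


def _module_index(network: HierarchicalNetwork):
    """0-based module id per node, module sizes and module -> population map."""
    labels1 = network.partition[0]
    blocks = np.unique(labels1)
    lookup = {b: i for i, b in enumerate(blocks)}
    mod_id = np.array([lookup[b] for b in labels1], dtype=np.int64)
    sizes = np.bincount(mod_id, minlength=blocks.size).astype(np.int64)
    pops = np.empty(blocks.size, dtype=np.int64)
    for b, i in lookup.items():
        pops[i] = network.partition[1][labels1 == b][0]
    return mod_id, sizes, pops


def _coupling_constant(
    network: HierarchicalNetwork, config: DynamicsConfig, k_target: Optional[float]
) -> float:
    if k_target is None:
        if network.probs is not None and network.probs.k_target is not None:
            k_target = network.probs.k_target
        else:
            k_target = network.mean_degree
    if k_target <= 0:
        raise ValueError("mean degree for coupling normalization must be positive")
    return config.K_numerator / k_target


def _wrap(theta: np.ndarray) -> np.ndarray:
    """Wrap phases to (-pi, pi]."""
    return math.pi - np.mod(math.pi - theta, 2 * math.pi)


def simulate(
    network: HierarchicalNetwork,
    config: DynamicsConfig,
    k_target: Optional[float] = None,
) -> PhaseTrajectory:
    """Integrate the equations of motion from i.i.d. U(-pi, pi) initial phases.

    Deterministic (bit-reproducible) for a fixed (network, config).  ``k_target``
    overrides the mean degree used in the coupling normalization; by default the
    generative target degree of the network is used.
    """
    N = network.N
    if N < 2:
        raise ValueError("need at least two oscillators")
    ss = np.random.SeedSequence(config.seed)
    ss_phase, ss_freq = ss.spawn(2)
    theta0 = np.random.default_rng(ss_phase).uniform(-math.pi, math.pi, N)
    omega = sample_frequencies(N, config.omega_mean, config.omega_sd, ss_freq)
    K = _coupling_constant(network, config, k_target)
    iptr_in, idx_in, iptr_lag, idx_lag = _split_edges(network)
    mod_id, sizes, pops = _module_index(network)
    n_rec = (config.total_steps - 1) // config.record_stride + 1
    theta_rec, S_re, S_im, theta_final = euler_ks(
        theta0,
        omega,
        K,
        config.dt,
        config.total_steps,
        iptr_in,
        idx_in,
        iptr_lag,
        idx_lag,
        math.cos(config.alpha),
        math.sin(config.alpha),
        mod_id,
        sizes.size,
        config.record_stride,
        n_rec,
    )
    if not np.isfinite(theta_final).all():
        bad = np.flatnonzero(~np.isfinite(S_re).all(axis=1))
        step = int(bad[0]) + 1 if bad.size else config.total_steps
        raise IntegrationDivergedError(f"non-finite phase at step {step}")
    times = np.arange(n_rec) * config.record_stride * config.dt
    return PhaseTrajectory(
        theta=_wrap(theta_rec),
        times=times,
        config=config,
        network=network,
        block_phasors=S_re + 1j * S_im,
        module_sizes=sizes,
        module_population=pops,
        k_effective=K,
        theta_final=theta_final,
    )


def reference_simulate(
    network: HierarchicalNetwork,
    config: DynamicsConfig,
    k_target: Optional[float] = None,
) -> PhaseTrajectory:
    """Dense-matrix integrator used as an independent oracle in tests.

    Realizes the lag via an explicit per-pair alpha matrix and vectorized numpy
    stepping; identical initial conditions and update rule as `simulate`.
    Intended for small networks / few steps only.
    """
    N = network.N
    ss = np.random.SeedSequence(config.seed)
    ss_phase, ss_freq = ss.spawn(2)
    theta = np.random.default_rng(ss_phase).uniform(-math.pi, math.pi, N)
    omega = sample_frequencies(N, config.omega_mean, config.omega_sd, ss_freq)
    K = _coupling_constant(network, config, k_target)
    A = network.adjacency.astype(float)
    same = network.partition[0][:, None] == network.partition[0][None, :]
    alpha = np.where(same, 0.0, config.alpha)
    mod_id, sizes, pops = _module_index(network)
    n_rec = (config.total_steps - 1) // config.record_stride + 1
    theta_rec = np.empty((n_rec, N))
    theta_rec[0] = theta
    rec_i = 1
    S = np.empty((config.total_steps, sizes.size), dtype=complex)
    for m in range(config.total_steps):
        diff = theta[None, :] - theta[:, None] - alpha  # diff[i, j]
        coupling = (A * np.sin(diff)).sum(axis=1)
        theta = theta + config.dt * (omega + K * coupling)
        z = np.exp(1j * theta)
        S[m] = np.bincount(mod_id, weights=z.real, minlength=sizes.size) + 1j * np.bincount(
            mod_id, weights=z.imag, minlength=sizes.size
        )
        nxt = m + 1
        if rec_i < n_rec and nxt % config.record_stride == 0:
            theta_rec[rec_i] = theta
            rec_i += 1
    times = np.arange(n_rec) * config.record_stride * config.dt
    return PhaseTrajectory(
        theta=_wrap(theta_rec),
        times=times,
        config=config,
        network=network,
        block_phasors=S,
        module_sizes=sizes,
        module_population=pops,
        k_effective=K,
        theta_final=theta,
    )
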