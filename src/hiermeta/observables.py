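"""Kuramoto order parameters and layer-resolved metastability indices.

The global Kuramoto order parameter (KOP) is Z = R e^{i psi} = <e^{i theta_j}>,
with R in [0, 1]; the local KOP restricts the average to a subset of
oscillators (a module, a population).  The metastability index of a layer is
the mean over its blocks of the temporal standard deviation of each block's
local KOP, computed on the post-relaxation window only; for the single-block
top layer this reduces to sigma(R_global).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .dynamics import PhaseTrajectory

__all__ = [
    "OrderParameterSeries",
    "MetastabilityReport",
    "global_kop",
    "local_kop",
    "layer_series",
    "layer_metastability",
    "population_stats",
    "metastability_report",
]


@dataclass
class OrderParameterSeries:
    """Per-step global and per-block local order parameters for one layer."""

    R_global: np.ndarray
    psi_global: np.ndarray
    R_local: Dict[int, np.ndarray]
    psi_local: Dict[int, np.ndarray]
    layer: int
    relax_steps: int


@dataclass
class MetastabilityReport:
    """sigma_met per layer plus per-population and per-block summaries."""

    sigma_met: Dict[int, float]
    per_population: Dict[int, float]
    mean_R: Dict[Tuple[int, int], float]


def global_kop(theta: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Modulus and argument of the mean unit phasor along the node axis."""
    theta = np.asarray(theta)
    if theta.size == 0:
        raise ValueError("empty phase array")
    Z = np.exp(1j * theta).mean(axis=-1)
    return np.abs(Z), np.angle(Z)


def local_kop(theta: np.ndarray, nodes) -> Tuple[np.ndarray, np.ndarray]:
    """KOP restricted to ``nodes``; with all nodes this equals `global_kop`."""
    nodes = np.asarray(nodes)
    if nodes.size == 0:
        raise ValueError("empty node set")
    return global_kop(np.asarray(theta)[..., nodes])


def _phasor_series(traj: PhaseTrajectory, layer: int):
    """Per-block phasor sums and sizes for ``layer``, from module phasors.

    Exact: the module phasor sums are accumulated at every integration step,
    and upper-layer phasors are their block sums.
    """
    S = traj.block_phasors
    sizes = traj.module_sizes
    if layer == 1:
        ids = np.arange(1, sizes.size + 1)
        return {int(b): S[:, i] for i, b in enumerate(ids)}, {
            int(b): int(sizes[i]) for i, b in enumerate(ids)
        }
    if layer == 2:
        pops = traj.module_population
        out, out_sizes = {}, {}
        for p in np.unique(pops):
            sel = pops == p
            out[int(p)] = S[:, sel].sum(axis=1)
            out_sizes[int(p)] = int(sizes[sel].sum())
        return out, out_sizes
    if layer == 3:
        return {1: S.sum(axis=1)}, {1: int(sizes.sum())}
    raise ValueError(f"layer must be 1, 2 or 3, got {layer}")


def layer_series(traj: PhaseTrajectory, layer: int) -> OrderParameterSeries:
    """Every-step local KOPs of all layer blocks, plus the global KOP."""
    phasors, sizes = _phasor_series(traj, layer)
    Zg = traj.block_phasors.sum(axis=1) / traj.module_sizes.sum()
    return OrderParameterSeries(
        R_global=np.abs(Zg),
        psi_global=np.angle(Zg),
        R_local={b: np.abs(z) / sizes[b] for b, z in phasors.items()},
        psi_local={b: np.angle(z) for b, z in phasors.items()},
        layer=layer,
        relax_steps=traj.config.relax_steps,
    )


def layer_metastability(series: OrderParameterSeries, layer: Optional[int] = None) -> float:
    """Mean over blocks of the temporal (population) SD of the local KOP.

    Computed on the post-relaxation window; for layer 3 this is sigma(R_global).
    """
    if layer is not None and layer != series.layer:
        raise ValueError(f"series holds layer {series.layer}, asked for {layer}")
    r = series.relax_steps
    if series.R_global[r:].size < 2:
        raise ValueError("post-relaxation window must hold at least 2 samples")
    return float(np.mean([np.std(R[r:]) for R in series.R_local.values()]))


def population_stats(
    R_rho1: np.ndarray, R_rho2: np.ndarray, relax_steps: int
) -> Tuple[float, float]:
    """Mean and SD of d(t) = |R_rho1(t) - R_rho2(t)| over the analysis window.

    The SD uses the population convention (divisor = window length), matching
    the 1/(T - r) normalization of the defining sums.
    """
    R_rho1 = np.asarray(R_rho1)
    R_rho2 = np.asarray(R_rho2)
    if R_rho1.shape != R_rho2.shape:
        raise ValueError("population series must have equal length")
    d = np.abs(R_rho1 - R_rho2)[relax_steps:]
    if d.size < 2:
        raise ValueError("analysis window must hold at least 2 samples")
    return float(d.mean()), float(d.std())


def metastability_report(traj: PhaseTrajectory) -> MetastabilityReport:
    """sigma_met for layers 1-3, per-population module metastability and mean R."""
    sigma_met: Dict[int, float] = {}
    mean_R: Dict[Tuple[int, int], float] = {}
    r = traj.config.relax_steps
    series1 = layer_series(traj, 1)
    for layer in (1, 2, 3):
        s = series1 if layer == 1 else layer_series(traj, layer)
        sigma_met[layer] = layer_metastability(s)
        for b, R in s.R_local.items():
            mean_R[(layer, b)] = float(R[r:].mean())
    per_population: Dict[int, float] = {}
    pops = traj.module_population
    module_ids = np.arange(1, traj.module_sizes.size + 1)
    for p in np.unique(pops):
        members = module_ids[pops == p]
        per_population[int(p)] = float(
            np.mean([np.std(series1.R_local[int(b)][r:]) for b in members])
        )
    return MetastabilityReport(
        sigma_met=sigma_met, per_population=per_population, mean_R=mean_R
    )
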