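"""Classification of population-layer states into chimera taxonomy.

With two populations rho1, rho2, the asymmetry series d(t) = |R_rho1 - R_rho2|
summarized by its mean d_bar and SD sigma(d) separates four regimes relative to
data-driven thresholds (delta1, delta2), each set 3 ensemble standard
deviations above the H=0 (no mesoscale structure) baseline mean:

    d_bar > delta1, sigma(d) < delta2  -> stable chimera
    d_bar > delta1, sigma(d) > delta2  -> breathing chimera
    d_bar < delta1, sigma(d) > delta2  -> metastable/alternating chimera
    otherwise                          -> coherent, unless both populations are
                                          internally coherent while mutually
                                          independent -> decoupled (region v)

The decoupled heuristic (the model has no formal rule for region v) requires
both populations' time-mean local KOP to exceed the H=0 ensemble-mean global R
and the circular SD of the population phase difference to exceed a threshold
(default 0.5 rad), indicating free mutual drift.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "ChimeraThresholds",
    "ChimeraStats",
    "LABELS",
    "baseline_thresholds",
    "classify",
    "circular_sd",
    "modal_label",
    "region_boundaries",
]

LABELS = (
    "coherent",
    "stable_chimera",
    "breathing_chimera",
    "metastable_chimera",
    "decoupled",
)


@dataclass(frozen=True)
class ChimeraThresholds:
    delta1: float
    delta2: float
    baseline_mean_d: float
    baseline_sd_d: float
    baseline_mean_sigma: float
    baseline_sd_sigma: float
    baseline_mean_R: Optional[float] = None
    multiplier: float = 3.0


@dataclass(frozen=True)
class ChimeraStats:
    d_bar: float
    sigma_d: float
    label: str
    stable_population: Optional[int] = None
    unstable_population: Optional[int] = None


def baseline_thresholds(
    ensemble: Sequence[Tuple[float, float]],
    baseline_mean_R: Optional[float] = None,
    multiplier: float = 3.0,
) -> ChimeraThresholds:
    """Thresholds from an H=0 ensemble of (d_bar, sigma(d)) pairs.

    delta_i = baseline mean + ``multiplier`` * sample SD (ddof=1) across seeds.
    ``multiplier`` defaults to 3; {2, 3, 4} mirror the sensitivity sweep.
    """
    arr = np.asarray(ensemble, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] != 2:
        raise ValueError("need an ensemble of >= 2 (d_bar, sigma_d) pairs")
    mean_d, mean_s = arr.mean(axis=0)
    sd_d, sd_s = arr.std(axis=0, ddof=1)
    return ChimeraThresholds(
        delta1=float(mean_d + multiplier * sd_d),
        delta2=float(mean_s + multiplier * sd_s),
        baseline_mean_d=float(mean_d),
        baseline_sd_d=float(sd_d),
        baseline_mean_sigma=float(mean_s),
        baseline_sd_sigma=float(sd_s),
        baseline_mean_R=baseline_mean_R,
        multiplier=multiplier,
    )


def circular_sd(angles: np.ndarray) -> float:
    """Circular standard deviation sqrt(-2 ln |<e^{i a}>|) of an angle series."""
    Rbar = np.abs(np.exp(1j * np.asarray(angles)).mean())
    Rbar = min(Rbar, 1.0)
    if Rbar == 0.0:
        return float("inf")
    return float(np.sqrt(-2.0 * np.log(Rbar)))


def classify(
    stats: Tuple[float, float],
    thresholds: ChimeraThresholds,
    mean_R_populations: Sequence[float],
    cross_circular_sd: Optional[float] = None,
    decoupled_circ_sd: float = 0.5,
    coherent_fraction: float = 0.95,
) -> ChimeraStats:
    """Label one run from its (d_bar, sigma_d) and population summaries.

    ``mean_R_populations`` are the time-mean local KOPs of the populations in
    population-id order; for stable/breathing labels the stable population is
    the one with the higher mean local KOP.  ``cross_circular_sd`` is the
    circular SD of psi_rho1 - psi_rho2 used by the decoupled heuristic (skipped
    when None or when no baseline mean R is available); populations count as
    internally coherent when their mean local KOP exceeds ``coherent_fraction``
    times the H=0 ensemble-mean R.
    """
    d_bar, sigma_d = float(stats[0]), float(stats[1])
    mean_R = np.asarray(mean_R_populations, dtype=float)
    hi = int(np.argmax(mean_R)) + 1
    lo = int(np.argmin(mean_R)) + 1
    if d_bar > thresholds.delta1:
        label = "stable_chimera" if sigma_d < thresholds.delta2 else "breathing_chimera"
        return ChimeraStats(d_bar, sigma_d, label, stable_population=hi, unstable_population=lo)
    if sigma_d > thresholds.delta2:
        return ChimeraStats(d_bar, sigma_d, "metastable_chimera")
    if (
        cross_circular_sd is not None
        and thresholds.baseline_mean_R is not None
        and cross_circular_sd > decoupled_circ_sd
        and np.all(mean_R > coherent_fraction * thresholds.baseline_mean_R)
    ):
        return ChimeraStats(d_bar, sigma_d, "decoupled")
    return ChimeraStats(d_bar, sigma_d, "coherent")


def modal_label(labels: Iterable[str]) -> str:
    """Most frequent label; ties broken by the fixed order of ``LABELS``."""
    labels = list(labels)
    if not labels:
        raise ValueError("empty label collection")
    counts = {lab: labels.count(lab) for lab in set(labels)}
    best = max(counts.values())
    for lab in LABELS:
        if counts.get(lab, 0) == best:
            return lab
    # labels outside the taxonomy: fall back to first-seen among the tied
    for lab in labels:
        if counts[lab] == best:
            return lab
    raise AssertionError("unreachable")


def region_boundaries(
    H_grid: Sequence[float], labels: Sequence[str]
) -> List[Tuple[float, float, str]]:
    """Maximal contiguous runs of identical labels on a monotone H grid.

    Returns (H_low, H_high, label) per run, with inclusive extents; a boundary
    grid point belongs to the lower-H run by construction (runs are maximal, so
    the first point of a new label starts the next run).
    """
    H_grid = list(H_grid)
    labels = list(labels)
    if not H_grid or len(H_grid) != len(labels):
        raise ValueError("H grid and labels must be nonempty and equal length")
    if any(b < a for a, b in zip(H_grid, H_grid[1:])):
        raise ValueError("H grid must be monotone nondecreasing")
    runs: List[Tuple[float, float, str]] = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((float(H_grid[start]), float(H_grid[i - 1]), labels[start]))
            start = i
    return runs
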