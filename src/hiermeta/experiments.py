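"""End-to-end sweeps over (H, k, seed) with counter-based seeded substreams.

A master seed spawns one `numpy.random.SeedSequence` per run, keyed by the run
coordinates (H, k, seed index, perturbation), so adding grid points never
shifts the random streams of existing runs and every record is a pure function
of (parameters, master seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import chimera, netgen, observables, spectral
from .dynamics import DynamicsConfig, simulate
from .netgen import HierarchyShape

__all__ = [
    "SweepSpec",
    "run_seeds",
    "run_single",
    "sweep",
    "baseline_run",
    "boundary_scan",
    "rewire_experiment",
    "frequency_experiment",
    "gap_cutoff_experiment",
]

_PERT_CODES = {"none": 0, "rewire": 1, "frequency": 2}


@dataclass(frozen=True)
class SweepSpec:
    """Declarative description of a sweep."""

    shape: HierarchyShape
    H_grid: Tuple[float, ...]
    k_grid: Tuple[float, ...]
    seeds: int
    dynamics: DynamicsConfig
    perturbation: str = "none"  # none | rewire | frequency
    perturbation_values: Tuple[float, ...] = (0.0,)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not self.H_grid or not self.k_grid:
            raise ValueError("grids must be nonempty")
        if self.seeds < 1:
            raise ValueError("seeds must be >= 1")
        if self.perturbation not in _PERT_CODES:
            raise ValueError(f"unknown perturbation {self.perturbation!r}")


def run_seeds(
    master_seed: int,
    H: float,
    k: float,
    seed_index: int,
    perturbation: str = "none",
    perturbation_value: float = 0.0,
) -> Tuple[int, int, int]:
    """(network, rewire, dynamics) integer sub-seeds for one run.

    Counter-based: the spawn key encodes the run coordinates, so streams are
    stable under grid extension.  All derived seeds are < 2^31.
    """
    key = (
        int(round(H * 10_000)),
        int(round(k * 10)),
        int(seed_index),
        _PERT_CODES[perturbation],
        int(round(perturbation_value * 1_000)),
    )
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=key)
    net_ss, rew_ss, dyn_ss = ss.spawn(3)
    return tuple(int(s.generate_state(1, np.uint32)[0] % 2**31) for s in (net_ss, rew_ss, dyn_ss))


def run_single(
    shape: HierarchyShape,
    H: float,
    k: float,
    dynamics: DynamicsConfig,
    master_seed: int,
    seed_index: int = 0,
    perturbation: str = "none",
    perturbation_value: float = 0.0,
    with_spectral: bool = True,
    with_modularity: bool = True,
) -> Dict[str, float]:
    """One full pipeline run: generate -> (perturb) -> simulate -> measure.

    Deterministic given all arguments.  The returned flat record carries every
    sweep column; the chimera label is attached later, once thresholds from the
    H=0 baseline ensemble are known.
    """
    # a zero-strength perturbation is the unperturbed system: same streams
    canonical = "none" if perturbation_value == 0 else perturbation
    net_seed, rew_seed, dyn_seed = run_seeds(
        master_seed, H, k, seed_index, canonical,
        perturbation_value if canonical != "none" else 0.0,
    )
    probs = netgen.connection_probabilities(H, shape, k_target=k)
    partition = netgen.build_partition(shape)
    network = netgen.sample_network(probs, partition, shape, net_seed)
    omega_sd = dynamics.omega_sd
    if perturbation == "rewire" and perturbation_value > 0:
        network = netgen.rewire(network, int(perturbation_value), rew_seed)
    elif perturbation == "frequency":
        omega_sd = float(perturbation_value)
    cfg = replace(dynamics, seed=dyn_seed, omega_sd=omega_sd)
    traj = simulate(network, cfg, k_target=k)
    report = observables.metastability_report(traj)
    s2 = observables.layer_series(traj, 2)
    pop_ids = sorted(s2.R_local)
    R1, R2 = (s2.R_local[p] for p in pop_ids[:2])
    d_bar, sigma_d = observables.population_stats(R1, R2, cfg.relax_steps)
    r = cfg.relax_steps
    dpsi = s2.psi_local[pop_ids[0]][r:] - s2.psi_local[pop_ids[1]][r:]
    record: Dict[str, float] = {
        "H": float(H),
        "k": float(k),
        "seed_index": int(seed_index),
        "perturbation": perturbation,
        "perturbation_value": float(perturbation_value),
        "mean_R_global": float(s2.R_global[r:].mean()),
        "sigma_met1": report.sigma_met[1],
        "sigma_met2": report.sigma_met[2],
        "sigma_met3": report.sigma_met[3],
        "d_bar": d_bar,
        "sigma_d": sigma_d,
        "mean_R_pop1": report.mean_R[(2, pop_ids[0])],
        "mean_R_pop2": report.mean_R[(2, pop_ids[1])],
        "sigma_met_pop1": report.per_population[pop_ids[0]],
        "sigma_met_pop2": report.per_population[pop_ids[1]],
        "cross_circular_sd": chimera.circular_sd(dpsi),
        "mean_R_modules": float(
            np.mean([report.mean_R[(1, b)] for b in range(1, shape.B1 + 1)])
        ),
    }
    if with_modularity:
        record["Q1"] = netgen.modularity(network, 1)
        record["Q2"] = netgen.modularity(network, 2)
    if with_spectral:
        profile = spectral.spectrum_of(network)
        record["gap1"] = profile.gap1
        record["gap2"] = profile.gap2
        record["a_prime"] = spectral.a_prime(network)
    return record


def _attach_labels(df: pd.DataFrame, thresholds: chimera.ChimeraThresholds) -> pd.DataFrame:
    labels = [
        chimera.classify(
            (row.d_bar, row.sigma_d),
            thresholds,
            (row.mean_R_pop1, row.mean_R_pop2),
            cross_circular_sd=row.cross_circular_sd,
        ).label
        for row in df.itertuples()
    ]
    out = df.copy()
    out["label"] = labels
    return out


def sweep(
    spec: SweepSpec,
    thresholds: Optional[chimera.ChimeraThresholds] = None,
    with_spectral: bool = True,
    existing: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Run all (H, k, seed, perturbation value) combinations of ``spec``.

    Rows already present in ``existing`` (matched by key columns) are reused,
    making long sweeps resumable.  When ``thresholds`` is given a chimera label
    column is attached.
    """
    key_cols = ["H", "k", "seed_index", "perturbation", "perturbation_value"]
    have = set()
    rows: List[Dict[str, float]] = []
    if existing is not None and len(existing):
        rows.extend(existing.to_dict("records"))
        have = {tuple(rec[c] for c in key_cols) for rec in rows}
    for pv in spec.perturbation_values:
        for H in spec.H_grid:
            for k in spec.k_grid:
                for s in range(spec.seeds):
                    key = (float(H), float(k), s, spec.perturbation, float(pv))
                    if key in have:
                        continue
                    rows.append(
                        run_single(
                            spec.shape,
                            H,
                            k,
                            spec.dynamics,
                            spec.master_seed,
                            seed_index=s,
                            perturbation=spec.perturbation,
                            perturbation_value=pv,
                            with_spectral=with_spectral,
                        )
                    )
    df = pd.DataFrame(rows).sort_values(key_cols).reset_index(drop=True)
    if thresholds is not None:
        df = _attach_labels(df, thresholds)
    return df


def baseline_run(
    shape: HierarchyShape,
    k: float,
    dynamics: DynamicsConfig,
    master_seed: int,
    seeds: int,
) -> chimera.ChimeraThresholds:
    """H=0 baseline ensemble -> chimera thresholds (and baseline mean R)."""
    records = [
        run_single(
            shape, 0.0, k, dynamics, master_seed, seed_index=s,
            with_spectral=False, with_modularity=False,
        )
        for s in range(seeds)
    ]
    pairs = [(rec["d_bar"], rec["sigma_d"]) for rec in records]
    mean_R = float(np.mean([rec["mean_R_global"] for rec in records]))
    return chimera.baseline_thresholds(pairs, baseline_mean_R=mean_R)


def _modal_labels(df: pd.DataFrame) -> Dict[float, str]:
    return {
        float(H): chimera.modal_label(list(g["label"]))
        for H, g in df.groupby("H", sort=True)
    }


def _refine_grid(lo: float, hi: float, step: float) -> List[float]:
    n = int(round((hi - lo) / step))
    return [round(lo + i * step, 10) for i in range(1, n)]


def boundary_scan(
    shape: HierarchyShape,
    k: float,
    dynamics: DynamicsConfig,
    master_seed: int,
    coarse_grid: Sequence[float],
    seeds: int = 10,
    baseline_seeds: Optional[int] = None,
    refine_step: float = 0.01,
    thresholds: Optional[chimera.ChimeraThresholds] = None,
) -> Dict[str, object]:
    """Locate the chimera onset and the end of the fluctuating region in H.

    The *onset* is found from modal labels on ``coarse_grid``: the first H
    whose modal label has d_bar > delta1 (stable/breathing), refined on a
    ``refine_step`` grid.  The *upper* boundary is where the seed-averaged
    sigma(d) drops below delta2 — the taxonomy's own separator between the
    breathing/metastable chimera regions and the quiescent decoupled regime —
    bracketed on the coarse grid and located on the refined grid.  (At small
    ensemble sizes the metastable band is rarely the modal label anywhere, so
    the ensemble-mean crossing is the robust estimate of the region end.)
    """

    cache: Dict[float, pd.DataFrame] = {}

    def runs_at(H: float) -> pd.DataFrame:
        if H not in cache:
            recs = [
                run_single(
                    shape, H, k, dynamics, master_seed, seed_index=s,
                    with_spectral=False, with_modularity=False,
                )
                for s in range(seeds)
            ]
            cache[H] = _attach_labels(pd.DataFrame(recs), thresholds)
        return cache[H]

    def modal_at(H: float) -> str:
        return chimera.modal_label(list(runs_at(H)["label"]))

    def mean_sigma_d(H: float) -> float:
        return float(runs_at(H)["sigma_d"].mean())

    if thresholds is None:
        thresholds = baseline_run(
            shape, k, dynamics, master_seed, baseline_seeds or seeds
        )
    coarse_grid = [float(H) for H in coarse_grid]
    coarse = {H: modal_at(H) for H in coarse_grid}
    chim = {"stable_chimera", "breathing_chimera"}

    onset = None
    onset_refined = None
    for i, H in enumerate(coarse_grid):
        if coarse[H] in chim:
            onset = H
            if i > 0:
                lo = coarse_grid[i - 1]
                onset_refined = onset
                for Hr in _refine_grid(lo, H, refine_step):
                    if modal_at(Hr) in chim:
                        onset_refined = Hr
                        break
            else:
                onset_refined = H
            break

    upper = None
    upper_refined = None
    delta2 = thresholds.delta2
    above_idx = [
        i for i, H in enumerate(coarse_grid) if mean_sigma_d(H) > delta2
    ]
    if above_idx and above_idx[-1] + 1 < len(coarse_grid):
        i_last = above_idx[-1]
        lo, hi = coarse_grid[i_last], coarse_grid[i_last + 1]
        upper = hi
        upper_refined = hi
        for Hr in _refine_grid(lo, hi, refine_step):
            if mean_sigma_d(Hr) < delta2:
                upper_refined = Hr
                break
    return {
        "thresholds": thresholds,
        "coarse_labels": coarse,
        "coarse_sigma_d": {H: mean_sigma_d(H) for H in coarse_grid},
        "onset_coarse": onset,
        "onset": onset_refined,
        "upper_coarse": upper,
        "upper": upper_refined,
    }


def rewire_experiment(
    shape: HierarchyShape,
    H: float,
    k: float,
    dynamics: DynamicsConfig,
    r_values: Sequence[int],
    seeds: int,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Structural robustness: metrics per rewiring count r at fixed (H, k)."""
    spec = SweepSpec(
        shape=shape,
        H_grid=(H,),
        k_grid=(k,),
        seeds=seeds,
        dynamics=dynamics,
        perturbation="rewire",
        perturbation_values=tuple(float(r) for r in r_values),
        master_seed=master_seed,
    )
    return sweep(spec)


def frequency_experiment(
    shape: HierarchyShape,
    H: float,
    k: float,
    dynamics: DynamicsConfig,
    delta_omega_values: Sequence[float],
    seeds: int,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Frequency-heterogeneity robustness: metrics per omega spread delta-omega."""
    spec = SweepSpec(
        shape=shape,
        H_grid=(H,),
        k_grid=(k,),
        seeds=seeds,
        dynamics=dynamics,
        perturbation="frequency",
        perturbation_values=tuple(float(d) for d in delta_omega_values),
        master_seed=master_seed,
    )
    return sweep(spec, with_spectral=False)


def gap_cutoff_experiment(
    shape: HierarchyShape,
    H: float,
    k_values: Sequence[float],
    dynamics: DynamicsConfig,
    seeds: int,
    master_seed: int = 0,
) -> Dict[str, object]:
    """Sweep k at fixed H; return ensemble means and the gap2 cutoff of sigma_met^1."""
    spec = SweepSpec(
        shape=shape,
        H_grid=(H,),
        k_grid=tuple(float(k) for k in k_values),
        seeds=seeds,
        dynamics=dynamics,
        master_seed=master_seed,
    )
    df = sweep(spec, with_spectral=True)
    agg = df.groupby("k", sort=True)[["gap2", "sigma_met1"]].mean().reset_index()
    cutoff = spectral.gap_metastability_cutoff(
        agg["gap2"].to_numpy(), agg["sigma_met1"].to_numpy()
    )
    return {"table": df, "aggregate": agg, "cutoff": cutoff}
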