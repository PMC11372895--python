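# hiermeta

Metastability and chimera states of frustrated Kuramoto–Sakaguchi oscillators
on hierarchically modular networks.

`hiermeta` is for researchers in oscillatory network dynamics and computational
neuroscience who want a fully seeded, end-to-end pipeline connecting a
*structural* control parameter of a hierarchical random graph to the
*dynamical* regimes (coherence, stable/breathing/metastable chimeras,
decoupling) of identical phase oscillators running on it, and to the spectral
quantities (Laplacian gaps, renormalization-group coarse-graining) that explain
those regimes.

## The model

**Networks.** A single-parameter variation of the nested stochastic block
model builds unweighted, undirected 3-layer graphs: `n1` nodes per *module*,
`n2` modules per *population*, `n3 = 2` populations (the two-hemisphere
configuration). With density factor γ ∈ [0, 1],

    p1(H) = 1 − (1−H)/2 · n1 γ/(n1−1)   (same module)
    p2(H) = (1+H)/2 · γ                 (same population, different module)
    p3(H) = (1−H)/2 · γ                 (different populations)

so the mean degree ⟨k⟩ = (n1−1) p1 + n1(n2−1) p2 + n1 n2 (n3−1) p3
= (n1−1) + γ n1 (n2−1) is independent of the structural parameter H ∈ [0, 1]:
H = 0 is a flat two-level SBM, H = 1 two fully decoupled populations, at
constant density. γ is solved from a target mean degree k ∈ [n1−1, n1·n2−1].

**Dynamics.** Each node is a Kuramoto–Sakaguchi oscillator

    dθi/dt = ωi + K Σj Aij sin(θj − θi − αij),   K = 50/⟨k⟩,

with identical frequencies ωi = 1 by default, and a layer-dependent phase lag:
αij = 0 inside a module and αij = α = π/2 − β across modules (β = 0.1).
Integration is explicit Euler, dt = 0.001, 55 000 steps with 5 000 steps of
relaxation excluded from all statistics.

**Observables.** Global and per-block Kuramoto order parameters
R = |⟨e^{iθ}⟩|; the layer-l metastability index σ_met^l = mean over layer-l
blocks of the temporal SD of the block's local KOP; the population asymmetry
d(t) = |R_ρ1 − R_ρ2| summarized by (d̄, σ(d)). Data-driven thresholds
δ1, δ2 (H = 0 baseline mean + 3 ensemble SD) classify each run as coherent,
stable chimera (d̄>δ1, σ(d)<δ2), breathing chimera (d̄>δ1, σ(d)>δ2),
metastable/alternating chimera (d̄<δ1, σ(d)>δ2), or decoupled.

**Spectra.** For the graph Laplacian L = D − A with eigenvalues
0 = λ1 ≤ … ≤ λN, the gaps λ_{B2+1} − λ_{B2} and λ_{B1+1} − λ_{B1} measure the
timescale separation between hierarchical layers. The Laplacian
renormalization group step keeps the B1 slow modes
(L′ = Σ_{λi<λ*} λi |λi⟩⟨λi|, λ* = λ_{B1+1}), projects onto module indicators
(A′_αβ = −⟨α|L′|β⟩, zero diagonal) and summarizes the resulting weighted
network by the two-population disparity a′ = (K1 − K2)/(K1 + K2).

## Worked example

```bash
hiermeta generate --n1 16 --n2 8 --n3 2 --H 0.2 --k 21 --seed 7 --out net/
# wrote N=256 network (2643 edges, mean degree 20.65) to net/

hiermeta lrg --net net/ --lambda-star auto --out lrg/
# {"K1": 6.412, "K2": 4.578, "a_prime": 0.167, "lambda_star": 15.222,
#  "gap1": 0.155, "gap2": 8.147}

hiermeta simulate --net net/ --beta 0.1 --K 50 --seed 7 --out run/
# run/summary.json:
#   sigma_met: {1: 0.0029, 2: 0.1343, 3: 0.0865}
#   d_bar: 0.2458   sigma_d: 0.1708   mean_R_global: 0.7062
```

Reading the numbers: at low degree (k = 21) the second spectral gap is wide
(8.15), so the 16 modules stay rigidly synchronized (σ_met¹ ≈ 0.003) while the
population layer carries a strong chimera-like asymmetry (d̄ ≈ 0.25 — one
population more coherent than the other, global R ≈ 0.71). The coarse-grained
network still resolves the two populations (K1 > K2, a′ ≈ 0.17 at H = 0.2).

The same pipeline is scriptable from Python:

```python
from hiermeta import HierarchyShape, DynamicsConfig
from hiermeta.experiments import run_single

rec = run_single(HierarchyShape(16, 8, 2), H=0.5, k=51.2,
                 dynamics=DynamicsConfig(), master_seed=1)
print(rec["sigma_met3"], rec["d_bar"], rec["gap2"])
```

`hiermeta sweep --config sweep.yaml --out results/` runs whole (H, k, seed)
grids, with rewiring and frequency-heterogeneity perturbations, and writes
long-format CSVs plus seed-aggregated summaries.

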