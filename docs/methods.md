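# Methods

## Generative model

The generator produces unweighted, undirected simple graphs with a three-layer
nested partition. Nodes are ordered block-contiguously; the partition matrix
P (3 × N) stores 1-based block ids, with row 3 constant (single top block).
Every unordered pair is an independent Bernoulli draw whose probability
depends only on the deepest layer in which the two nodes share a block
(standard stochastic-block-model sampling; no degree correction):

- p1(H) = 1 − (1−H)/2 · n1γ/(n1−1) within modules,
- p2(H) = (1+H)/2 · γ within populations,
- p3(H) = (1−H)/2 · γ across populations.

These are the unique simple forms satisfying the model's five constraints:
p2(0) = p3(0) (H = 0 degenerates to a flat two-level SBM), p3(1) = 0 (full
decoupling), p1 → 1 as γ → 0 (near-clique modules), ⟨k⟩ independent of H, and
⟨k⟩ spanning [n1−1, n1n2−1] as γ goes from 0 to 1. The closed form
⟨k⟩ = (n1−1) + γ·n1·(n2−1) is inverted exactly for γ given a target degree;
if a (H, γ) combination pushes p1 outside [0, 1] the generator raises instead
of clipping, since clipping would silently break degree conservation.
Note that p1 ≥ p2 is only guaranteed for γ ≤ 2(n1−1)/(2n1−1) ≈ 0.97; all
study densities (γ ≤ 0.47) are far inside this region.

**Study system.** n1 = 16, n2 = 8, n3 = 2, hence N = 256, B1 = 16 modules,
B2 = 2 populations, and admissible mean degrees 15 ≤ k ≤ 127. The reference
density is k = N/5 = 51.2 (γ ≈ 0.323); k = 21 (γ ≈ 0.054) exemplifies the
low-degree regime with near-clique modules.

**Controls.** `rewire` applies single-endpoint moves (pick an edge, keep one
endpoint at random, reattach to a uniform non-adjacent target), conserving the
edge count but not the degree sequence; a degree-preserving double-edge swap
is available via a flag. `configuration_model_control` delegates to
`networkx.random_regular_graph`: a uniform degree sequence with resampled stub
matching, valid whenever N·k is even, carrying a partition only for lag
assignment. `modularity` implements Newman's Q directly (vectorized) and is
cross-checked against networkx in the test suite.

## Dynamics

Each node carries a phase θi evolving under

    dθi/dt = ωi + K Σj Aij sin(θj − θi − αij).

The **attractive sign convention** is a deliberate choice: with the opposite
sign the zero-lag intra-module coupling is repulsive and modules can never
synchronize, contradicting every regime this package is built to study.
The Sakaguchi lag is pairwise and layer-dependent — αij = 0 when i and j share
a module, αij = α = π/2 − β otherwise — modelling shorter effective delays
inside spatially compact modules. β defaults to 0.1 rad (strong frustration);
β = π/2 recovers the unfrustrated Kuramoto model. Oscillators are identical
(ωi = 1) unless a normal spread N(1, δω) is requested. The coupling
K = 50/⟨k⟩ is normalized by the *target* mean degree, making different
densities comparable; normalizing by the realized degree instead changes K by
O(1/√N) and is available by passing `k_target=None` on a network without
generative metadata.

**Integration.** Explicit Euler with dt = 0.001 over 55 000 steps, the first
5 000 excluded from all statistics. Initial phases are i.i.d. U(−π, π).
A test verifies that halving dt leaves post-relaxation summaries unchanged;
with identical oscillators K rescales time exactly (K·dt invariance, tested
bitwise). The production stepper is a numba kernel over intra-/inter-module
edge lists that accumulates per-module phasor sums every step; a dense
pure-numpy integrator realizing the per-pair lag matrix literally serves as
the independent oracle in the tests (agreement to 1e−9 over hundreds of
steps). Runs are bit-reproducible for a fixed (network, config) pair: the
config seed spawns separate substreams for initial phases and frequencies.

**Memory/recording.** Raw phases are recorded every `record_stride` steps
(default 50) and wrapped to (−π, π]; order parameters at every layer derive
*exactly* from the per-step module phasor sums (the global phasor is the
size-weighted mean of block phasors — an identity, not an approximation — so
full-resolution statistics never require storing full phase trajectories).

## Metastability and chimera classification

σ_met^l is the mean over layer-l blocks of the temporal standard deviation of
the block's local KOP on the post-relaxation window; for the single-block top
layer it reduces to σ(R_global). Standard deviations over time use the
population convention (divisor = window length), matching the 1/(T − r)
normalization of the defining sums; ensemble statistics across seeds use the
sample convention (ddof = 1, small ensembles).

The population asymmetry d(t) = |R_ρ1(t) − R_ρ2(t)| is summarized by its mean
d̄ and SD σ(d). Thresholds are data-driven: δ1 (δ2) is the H = 0 ensemble mean
of d̄ (σ(d)) plus 3 ensemble SDs; the multiplier is tunable ({2, 3, 4} for
sensitivity analyses). Classification per run:

| d̄ vs δ1 | σ(d) vs δ2 | label |
|---|---|---|
| > | < | stable chimera |
| > | > | breathing chimera |
| < | > | metastable/alternating chimera |
| < | < | coherent, or decoupled (below) |

For stable/breathing states the *stable population* is the one with the higher
time-mean local KOP. The **decoupled** label (two internally coherent,
mutually independent populations) has no formal definition in terms of
(d̄, σ(d)); the heuristic used here requires both populations' time-mean local
KOP to exceed `coherent_fraction` (default 0.95) times the H = 0 ensemble-mean
global R, and the circular SD of the population phase difference ψ_ρ1 − ψ_ρ2
to exceed 0.5 rad (free mutual drift). Both knobs are exposed; the default
margin exists because at high H the population KOP sits within a few percent
of the H = 0 global KOP, making a strict comparison fragile.

A single `metastable_chimera` label covers both irregular and alternating
switching; an alternation score was considered and dropped from
classification because the (d̄, σ(d)) plane does not separate the two and no
acceptance-level quantity depends on the distinction.

**Region boundaries.** Sweeping H at fixed k, each grid point gets the modal
label over seeds (ties resolved by a fixed taxonomy order). The chimera
*onset* is the first H whose modal label has d̄ > δ1 (stable or breathing).
The *upper boundary* — where the breathing/metastable fluctuation region gives
way to the quiescent decoupled regime — is reported as the H at which the
seed-averaged σ(d) drops below δ2, the taxonomy's own separator for that
transition. A modal-label criterion is too brittle here: the metastable band
proper is narrow in this model (ensemble-mean d̄ and σ(d) cross their
thresholds almost simultaneously near H ≈ 0.6), so at 5–10 seeds the
metastable label is rarely modal at any grid point and label-based region ends
jump by a full grid cell between master seeds, while the mean-σ(d) crossing is
stable. Both boundaries are bracketed on a 0.05 grid and located on a 0.01
grid with the same ensemble size.

## Spectral analysis and coarse-graining

`spectrum` performs a full dense symmetric eigendecomposition of L = D − A
(scipy `eigh`; N = 256 costs ~50 ms). gap1 = λ_{B2+1} − λ_{B2} separates the
global mode from the two population modes and grows with H; gap2 =
λ_{B1+1} − λ_{B1} separates the B1 slow modes from the intra-module bulk and
shrinks as k grows.

The LRG step truncates the spectral resolution of L at λ* (default λ_{B1+1}),
keeping modes with λi < λ* strictly; if the boundary is degenerate to 1e−9 the
first B1 modes are kept by index. A′_αβ = −⟨α|L′|β⟩ with unnormalized 0/1
module indicators and a zeroed diagonal; at λ* = ∞ this reduces exactly to the
inter-module edge-count matrix (tested by brute force). K1/K2 average the
off-diagonal block couplings within/across populations and
a′ = (K1 − K2)/(K1 + K2), the two-population disparity, which is invariant
under uniform rescaling of A′ (so indicator normalization is irrelevant at
equal block sizes). The alternative normalization (K1 − K2)/K1 was rejected:
it is not symmetric in the two coupling classes and does not map the
decoupled limit to a′ = 1 from below in the same way.

**Validity domain of the slow-mode projection.** The projection is meaningful
when the module-indicator subspace is spanned by the retained modes, i.e. when
gap2 is open (low k): there a′(H) is almost exactly linear (R² > 0.99 at
k = 21). When the bare module eigenvalue k − [(n1−1)p1 − n1p2] sits inside the
Laplacian bulk (k ≳ 40 for the study shape), the module modes hybridize with
intra-module bulk modes, the retained set captures only part of the
within-population coupling while the (always retained) population mode pins
the cross-population coupling, and a′ from slow modes becomes small or
negative — the projection stops being a faithful two-population reduction.
For that dense regime `lrg_rescale(..., modes="fast")` reconstructs A′ from
the discarded fast modes instead (the short-timescale connectivity, in which
cross-population coupling is strongly suppressed and a′ approaches 1); it is
provided for exploration and comparison, while all default pipelines and
reported quantities use the slow-mode construction.

**Gap–metastability cutoff.** Sweeping k at fixed H yields paired ensemble
means (gap2, σ_met¹). On the log-log curve, the plateau level is the mean σ of
the two smallest-gap points and the floor the mean of the two largest-gap
points; the cutoff is where the piecewise-linear log-log curve crosses the
geometric midpoint of the two levels (the half-way point on the log scale).
On symmetric step data this lands exactly at the geometric centre of the
collapse; on the study sweep it localizes the collapse near gap2 ≈ 2.
A curve that never crosses returns "no cutoff" rather than an error.

## Seeding and ensembles

A master seed spawns one `SeedSequence` per run, keyed by the rounded run
coordinates (H, k, seed index, perturbation type and strength), so extending a
grid never shifts existing streams and every sweep is a pure function of
(spec, master seed). Zero-strength perturbations are canonicalized to the
unperturbed key, making r = 0 and δω = 0 reproduce baseline records bitwise.
All derived integer seeds are below 2³¹.

Ensemble sizes are a speed/precision trade-off: the acceptance script uses 10
seeds per parameter point (5 per point for the six-density cutoff sweep) and
the test suite 2–5 seeds on focused parameter windows; at these sizes the
seed-to-seed SD of the time-mean global KOP is ≈ 0.02–0.04, so reported means
carry standard errors of ~0.01–0.02. Full-scale sweeps (100 seeds, full
grids) are available through `hiermeta sweep --preset paper`.

## What the generator does and does not emulate

The synthetic networks are homogeneous by construction: unimodal degrees, no
hubs, rich club, spatial embedding, weights or delays — mesoscale hierarchy is
the *only* structural feature, which is exactly what makes the H → dynamics
mapping interpretable. Consequently, passing tests demonstrate that nested
modularity alone produces and organizes these regimes in this model class;
they say nothing about systems whose metastability is driven by degree
heterogeneity, coupling weights, conduction delays, or noise, and empirical
connectomes differ in all four respects.

## Known limitations

- Region boundaries are modal-label estimates; with ≤ 10 seeds the
  metastable band (d̄ < δ1 with σ(d) > δ2) is often not the modal label at any
  grid point even though individual seeds show it, hence the fluctuation-set
  definition of the upper boundary above.
- At H just above the decoupling threshold the two populations may lock at a
  large phase offset instead of drifting; the global KOP then underestimates
  the "two independent coherent populations" picture, and the decoupled label
  triggers only once drift sets in (H ≳ 0.9 at k = 51.2).
- The slow-mode LRG disparity is only quantitative at low density (open
  gap2); see the validity-domain discussion above.
- Explicit Euler at dt = 0.001 is the convention adopted throughout; the
  dt-halving test guards the default parameter region, not arbitrary (K, β).
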