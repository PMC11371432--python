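# Methods

## Model

Agents are self-propelled particles at constant speed `v0` on the d-torus
`[0, L)^d`, `L = (N/ρ)^(1/d)`, with unit time step and synchronous updates:
all new velocities are computed from time-t quantities, then all positions
advance by the *new* velocity and wrap (the standard forward Vicsek update).
Distances are Euclidean distances between nearest periodic images,
per-axis `δ − L·round(δ/L)`, valid up to `L/2` per axis.

Each step the swarm is embedded in a Vietoris–Rips complex at filtration
radius `rmax` (inclusive threshold, edges only by default). The complex
spans the *entire* swarm, including pairs closer than `rmin`: the annulus
restricts which agents are eligible neighbours, not which edges exist —
curvature is a global property of the configuration. A flag
(`exclude_short_edges`) drops sub-`rmin` edges for sensitivity analysis.

Weights are `w_i = 1 + degree(i)` and `w_ij = (w_i + w_j)/(1 + r_ij)`.
The weighted Forman–Ricci curvature of an edge `a = (u, v)` is

    R_a = (w_u + w_v) − Σ_{a' ∥ a} w_g / sqrt(w_a w_a') · w_a,

the parallel sum running over edges `a'` sharing exactly one vertex `g`
with `a`. The printed form of this parallel term is typographically
ambiguous in parts of the literature; the reading used here is the standard
weighted Forman form and the only one that reduces to the classical
`4 − deg(u) − deg(v)` at unit weights, which the test suite verifies
exhaustively on all labeled graphs with ≤ 5 vertices. With the complex
truncated at edges there are no upper-adjacency (triangle) contributions.
Vertex curvature is `R_i = Σ_{a ∋ i} R_a`, so `Σ_i R_i = 2 Σ_a R_a`.

Update rule (curvature mode): candidates of agent i are all j ≠ i with
`rmin ≤ d(i,j) ≤ rmax` (closed interval; the boundary has measure zero but
the convention is fixed for determinism). The `min(k, #candidates)`
candidates with the smallest `R_i` are selected — always the smallest, even
when every candidate curvature is positive — with ties broken toward the
lower agent index. The new heading is the vertex-weight-weighted mean of
the selected velocities, renormalized to `v0`, plus a noise kick
`v0 η r̂`, renormalized to `v0` again. The weighted-mean equation alone
does not conserve speed at `η > 0`, while the model demands constant speed;
renormalizing after the kick makes noise a pure heading perturbation whose
turning angle is controlled by `η` (η = 1 allows up to 90° in 2D). An
agent with no candidates, or whose weighted sum cancels exactly, keeps its
own heading (plus noise); this fallback preserves speed and continuity and
is exercised rarely except in very sparse configurations.

Vicsek baseline (`mode="vicsek"`): unweighted mean over the metric
neighbourhood *including the agent itself* (the classical convention; it
also makes the all-to-all zero-noise system reach consensus in exactly one
step), then the same noise and renormalization.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `N` | agents | 100 (2D) | reference 2D ensemble size |
| `rho` | number density (agents/length^d) | 1.0 | reference density; fixes `L` |
| `v0` | speed (length/step) | 0.5 | reference speed |
| `eta` | noise strength (dimensionless) | 0.0 | noiseless baseline |
| `rmin, rmax` | annulus radii (length) | 0, 1 | unit-width annulus; `rmin=1` is the non-local variant |
| `k` | effective neighbour count | 1 | the economical single-neighbour rule |
| `steps` | time steps | 5000 | order saturates within a few hundred steps; 5000 leaves a long saturated window (the long-run presets use 1e5) |
| `samples` | independent runs | 10 | ensemble averaging; sample s uses seed `seed + s` |
| `hodge_beta` | entropy damping β | 1.0 | a neutral scale between the β→0 (ln #simplices) and β→∞ (ln Betti) limits; no canonical value exists for this model |
| `record_every` | observable cadence | 10 | order parameter and mean curvature are cheap |
| `topology_every` | entropy/Betti cadence | 0 (off) | the eigenproblem dominates step cost; enable for entropy studies |
| `dr`, `gr_window` | g(r) bin width / trailing window | 0.1, 0.2 | bins cover (0, L/2]; g(r) pooled over the saturated tail |

The 3D desk preset uses N = 200 at ρ = 1 (L ≈ 5.85); the full-protocol
presets (N = 1000, 1e5 steps) reproduce the reference conditions at
roughly 100× the cost.

## Numerics

- **Spectra.** All Laplacian eigenproblems use the dense symmetric solver;
  complexes stay well under a few thousand simplices at desk scale. For
  triangle-free complexes the edge-Laplacian spectrum is obtained from the
  graph Laplacian: `B₁ᵀB₁` and `B₁B₁ᵀ` share their nonzero spectrum, so
  L[1]'s eigenvalues are the nonzero graph-Laplacian eigenvalues plus
  exactly β₁ zeros. The zero eigenvalues are stripped *by count* (the graph
  Laplacian has exactly β₀ of them), not by thresholding. The dense and
  shortcut routes are cross-checked in the test suite.
- **Entropy** is evaluated in the eigenbasis (`S = β⟨λ⟩ + ln Z`), which is
  numerically stable for large β where the density-matrix form underflows;
  both forms agree to 1e−8 where both are computable. The entropy of an
  empty simplex order is defined as 0 with a warning.
- **Betti numbers** come from boundary ranks: β₀ via connected components
  (exact integer graph traversal), rank(B₂) via dense matrix rank when
  triangles are enabled. The Euler characteristic is computed both from
  Betti numbers and from alternating simplex counts and asserted equal.
- **Boundary orientation** follows sorted vertex order with lexicographic
  simplex ordering, making boundary matrices (and therefore every spectrum)
  reproducible across runs. `∂∂ = 0` is verified in integer arithmetic.
- **Determinism.** One `numpy` PCG64 generator per sample drives
  initialization and noise; batch noise draws consume the stream exactly as
  per-agent sequential draws, so the vectorized stepping loop is
  bit-identical to the reference single-agent update rule (tested).

## What the simulations do and do not show

The initial conditions emulate a maximally disordered swarm: positions
uniform in the box, headings isotropic. No attraction/repulsion forces,
body size, vision cones or inertia are modelled, so passing tests show the
topological interaction rule's ordering behaviour under the stated
idealizations — not that real flocks follow curvature gradients.

**Finite-size metastability.** At zero noise with k = 1 the update is a
pure velocity copy, so the set of headings present can only shrink;
consensus is a coalescence process. At desk scale (notably the 3D
non-local case at N = 200) a minority of seeds freezes into two
internally-aligned flocks sliding past each other in slabs, each agent's
lowest-curvature candidate lying in its own flock — an absorbing state
with order parameter well below 1 that persists indefinitely. The
ensemble-mean terminal order parameter therefore sits slightly below 1
when such a seed occurs. The state requires the flock interface to span
the box coherently, so it is a small-system phenomenon; the test suite
pins one such seed deterministically. This is a property of the
scaled-down system, not a numerical failure, and ensemble checks of the
3D non-local case should be read with that in mind.

## Limitations

- Simplices above dimension 2, persistent homology and normalized
  Laplacians are out of scope; entropy orders above 1 require `max_dim=2`.
- Non-cubic boxes and open boundaries are not supported.
- The annulus inner radius interacts with the complex only through
  neighbour candidacy (default); the alternative convention is available
  but untested against any reference behaviour.
- CPU only; the dense 3D full protocol (N = 1000, 1e5 steps) is hours, not
  minutes.
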