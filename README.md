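# ricciflock

Curvature-driven collective motion in periodic boxes, for researchers in
active matter and collective animal behaviour who want a minimal,
reproducible testbed for *topological* interaction rules.

## The model

`N` self-propelled agents move at constant speed `v0` in a periodic box of
edge `L = (N/ρ)^(1/d)` (d = 2 or 3). At every time step the whole swarm is
embedded in a Vietoris–Rips complex at filtration radius `rmax` under the
minimum-image metric, and weighted:

    w_i  = 1 + degree(i)                 (vertex weight)
    w_ij = (w_i + w_j) / (1 + r_ij)      (edge weight)

Every edge gets a weighted Forman–Ricci curvature (FRC); with unit weights
it reduces to the classical `4 − deg(u) − deg(v)`. The vertex curvature
`R_i = Σ_j R_ij` sums over incident edges; strongly negative `R_i` marks an
information hub. Each agent then looks at the candidates inside an annulus
`rmin ≤ r ≤ rmax` around itself (`rmin > 0` is the *non-local* variant that
ignores the closest agents), picks the `k` candidates with the **lowest**
`R_i`, and reorients along their vertex-weight-weighted mean heading:

    v_i(t+1) = v0 · Σ w_j v_j(t) / ‖Σ w_j v_j(t)‖ + v0 η r̂_i(t),

renormalized to speed `v0` (noise `η` perturbs heading only). The classical
Vicsek rule (unweighted metric-ball average) is available as a baseline
(`mode="vicsek"`).

Observables: the polar order parameter `⟨φ_v⟩ = ‖Σ v_i/‖v_i‖‖/N`, the mean
vertex FRC, the radial distribution function `g(r)`, Betti numbers
(β₀ = components, β₁ = independent loops) and Hodge spectral entropies

    S_n = β⟨λ_n⟩ + ln Z_n,   Z_n = Σ_i e^{−βλ_i(L[n])},

the von Neumann entropy of the Gibbs density matrix of the Hodge Laplacian
`L[n]` on n-simplices (`L[0]` is the graph Laplacian; `dim ker L[n] = β_n`).

The headline behaviour: at zero noise, following even a **single** most
negatively curved neighbour drives the swarm to complete order (`φ_v → 1`),
locally (`rmin = 0`) and non-locally (`rmin = 1`), in 2D and 3D.

## Worked example

```python
from ricciflock import SimConfig, run

cfg = SimConfig(N=100, d=2, rho=1.0, v0=0.5, eta=0.0,
                rmin=0.0, rmax=1.0, k=1, steps=5000, samples=10, seed=0)
result = run(cfg)
phi = [s.terminal_mean("phi_v", 0.2) for s in result.samples]
print("terminal <phi_v> per seed:", [round(p, 4) for p in phi])
```

prints

```
terminal <phi_v> per seed: [1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0]
```

every seed of the local 2D model at zero noise reaches complete alignment
(order parameter 1.0, averaged over the final 20 % of steps) with just one
effective neighbour. With `eta=0.2` the same ensemble gives ≈ 0.92 for
`k=1` and ≈ 0.96 for `k=7`: noise disrupts order, and more effective
neighbours resist it better.

The same is available from the shell:

```bash
ricciflock simulate --preset 2d-local --eta 0.2 --nn 7 --outdir out/
ricciflock sweep --preset 2d-local --param eta --values 0,0.1,0.2,0.4 --outdir sweep/
ricciflock analyze-cloud points.csv --radius 1.0     # curvature/Betti/entropy of a CSV cloud
ricciflock fixtures                                  # hand-checkable reference complexes
```

`simulate` writes per-sample and mean observable CSVs
(`step, phi_v, mean_R, S0, S1, betti0, betti1`), an optional `g(r)` table
and a JSON echo of the configuration with the seeds used.

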