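# netsparse

Which network topologies are cheap to control once every feedback channel
has a price?

Many biological networks — protein interaction maps, gene-regulatory
systems — are undirected, sparse, modular or hub-dominated, and are
regulated by feedback rather than open-loop control. Classical structural
controllability says such heterogeneous networks are *hard* to control
(they need many driver nodes). This package studies the complementary,
feedback-centric question for networks with Laplacian dynamics: when the
communication links between sensors and actuators are costly, which
topology minimizes the *total* price of disturbance rejection?

## The model

For an undirected simple graph with Laplacian `L = D − A`, the node states
obey

```
dx/dt = −L x + B1 d + B2 u,     u = −F x,
```

with `B1 = B2 = I`. The closed loop `dx/dt = −(L+F) x + B1 d` is scored by
the H2 norm of the disturbance-to-performance channel,

```
J(F) = trace(B1ᵀ P B1),   −(L+F)ᵀP − P(L+F) + (I + FᵀF) = 0,
```

and every nonzero entry of `F` is a feedback channel costing `γ`, giving
the sparsity-promoting design problem

```
minimize  J(F) + γ · card(F).
```

The nonconvex cardinality term is handled by ADMM (Anderson–Moore F-step,
hard-thresholding G-step, projected-gradient polishing of the final
pattern), warm-started along an increasing γ homotopy from the closed-form
centralized optimum `F* = −L + (L² + I)^{1/2}`.

Test networks (100 nodes, 300 edges) are grown by heat-kernel adaptive
rewiring: a pivot node cuts its weakest-diffusion edge and connects to its
strongest-diffusion non-neighbor, where diffusion is `exp(−τ·𝓛̂)` on the
normalized Laplacian. The diffusion scale τ selects the topology — τ=0
random (ER), τ≈1 modular, τ≈10 centralized/star-like. Topology is measured
by Newman–Girvan modularity `Q` (Leiden maximization, degree-preserving
null normalization), the degree-distribution standard deviation σ
(centralization), and the minimum driver-node count `n_D` (maximum
geometric multiplicity of adjacency eigenvalues, the PBH test).

## Worked example

```python
import numpy as np
from netsparse import (RewiringConfig, generate_ensemble, find_communities,
                       modularity, degree_stats, min_driver_nodes,
                       laplacian, solve_gamma_path)

g = generate_ensemble(RewiringConfig(tau=1.0, seed=1, n_samples=1))[-1]
print(modularity(g, find_communities(g, 0)))   # 0.8203  (modular regime)
print(degree_stats(g).degree_std)              # 1.064   (homogeneous degrees)
print(min_driver_nodes(g).n_driver)            # 20      (drivers per PBH test)

sols = solve_gamma_path(laplacian(g), [1e-4, 1e-2, 1e-1])
for gam, s in zip([1e-4, 1e-2, 1e-1], sols):
    print(f"gamma={gam:g}  J={s.costs.J:.2f}  card={s.costs.card}  total={s.costs.total:.2f}")
# gamma=0.0001  J=16.16  card=3360  total=16.50
# gamma=0.01    J=16.18  card=1516  total=31.34
# gamma=0.1     J=16.28  card=930   total=109.28
```

A modular network reaches essentially its dense performance (`J ≈ 16.2`)
while shedding channels into its communities as γ rises: card drops from
3360 (of 10000) to 930 while J moves by less than 1%.

## The analysis

Numbered drivers under `analysis/` reproduce the study end to end and
write their tables to `results/`:

1. `01_generate_networks.py` — ensembles for τ ∈ {0..10}; modularity rises
   to ≈0.85 by τ=1 and collapses into hub-dominance (σ ≈ 12) by τ=9–10.
2. `02_null_normalization.py` — modularity against degree-preserving
   nulls: τ=0 is chance-level (ratio ≈ 0.99), τ=1 is not (ratio ≈ 2.2).
3. `03_sparse_control_sweep.py` — mean total cost by topology and γ: the
   cheapest-to-control topology flips as γ rises:

   ```
   gamma= 0.0001: cheapest=random       random=  13.91  modular=  17.03  centralized=  31.46
   gamma= 0.0100: cheapest=modular      random=  42.69  modular=  31.25  centralized=  35.50
   gamma= 0.1000: cheapest=centralized  random=  95.31  modular= 108.67  centralized=  65.82
   ```

4. `04_correlations.py` — Spearman correlations: degree spread σ raises
   the performance cost at every γ (ρ(σ,J) = +0.77) while shedding
   channels, so the σ–total-cost correlation flips sign as channels get
   expensive (+0.77 → −0.08 → −0.73 across the three γ); modularity
   behaves analogously at moderate γ (ρ(Q,J) = +0.85, ρ(Q,card) = −0.97);
   driver nodes rise with both σ (ρ = +0.93) and Q (ρ = +0.83).

A `netsparse` CLI (`generate`, `metrics`, `control`, `drivers`, `sweep`,
`report`) exposes the same operations on edge-list files.

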