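# Methods

## Network generation by adaptive rewiring

Networks are undirected simple graphs with `N = 100` nodes and `E = 300`
edges (density `ρ = 2E/(N²−N) = 0.061`, mean degree `k = 2E/N = 6`),
initialized as uniform Erdős–Rényi `G(N, E)` draws and evolved for 600
rewiring steps. Each step picks a pivot node uniformly among nodes with at
least one neighbor and one non-neighbor (ineligible pivots are redrawn, up
to 10·N times before the graph is declared degenerate). With probability
`p = 0.10` the pivot cuts a uniformly random incident edge and connects to
a uniformly random non-neighbor; otherwise it cuts the neighbor `j`
minimizing `h[i,j]` and connects the non-neighbor `k` maximizing `h[i,k]`,
where `h = exp(−τ·𝓛̂)` is the heat kernel of the symmetric normalized
Laplacian `𝓛̂ = I − D^{−1/2} A D^{−1/2}` (rows/columns of isolated nodes
zeroed, so they neither emit nor absorb heat). Ties at the extremal kernel
value are broken uniformly with the step's RNG. The kernel is recomputed
after every step by default (`kernel_refresh` relaxes this); it is
evaluated through the eigendecomposition of 𝓛̂ rather than a general
matrix exponential, which at N = 100 is both faster and exactly symmetric.

The diffusion scale τ is the only knob that matters: at τ=0 the kernel is
the identity, every kernel comparison is a tie, and the graph performs a
uniform random walk over edge configurations (it stays ER); at τ≈1 heat is
trapped in local neighborhoods and modules condense (Q rises from ≈0.39 to
≈0.85); at τ≈10 the kernel is dominated by the slowest global modes and
edges pile onto a few hubs (degree-σ ≈ 12 with mean degree 6). The
transition region sits near τ≈7–8 and exhibits large run-to-run variance.

Ensembles: a single 600-step run snapshotted every `n_steps/n_samples`
steps reproduces the original sampling scheme ("trajectory" mode), mixing
early ER-like snapshots with late formed structure; independent runs
keeping only the final snapshot ("final" mode) give well-formed exemplars
of each topology class. The regime-ordering analysis uses final mode (its
question is about formed topologies); the correlation analysis uses
trajectory mode, because the metric spread along the formation path is
exactly what those correlations are computed over — with final-mode
samples at a single τ, degree-σ is nearly constant and its correlations
are dominated by sampling noise.

Null models are degree-preserving double-edge swaps (default 10·E
attempted swaps; illegal swaps skipped, so e.g. complete graphs return
unchanged). Normalized modularity is the ratio `Q / mean(Q_null)` over
≥10 nulls, each null re-partitioned from scratch; a z-score is emitted
alongside as a secondary statistic.

## Topology metrics

Degree statistics use the sample standard deviation (denominator N−1).
Modularity is Newman–Girvan `Q = Σ_c [e_c/E − (d_c/2E)²]`, evaluated by
networkx and maximized by Leiden (modularity objective) with 5 seeded
restarts, keeping the best-Q partition; on graphs of ≤8 nodes the result
matches exhaustive search over all set partitions to 1e−12. Driver nodes
use the PBH criterion for symmetric adjacency matrices: the count is the
maximum eigenvalue multiplicity, obtained by clustering sorted eigenvalues
with gap tolerance `1e−8 · N · max|λ|`. Integer symmetric matrices at
N=100 have distinct-eigenvalue gaps many orders above this tolerance, so
the clustering is insensitive to its exact value; the tolerance is
exposed for unusual inputs.

## Feedback design

The H2 cost and its machinery follow the standard LQR/Gramian toolkit:
`J(F) = trace(B1ᵀPB1)` with P from the closed-loop Lyapunov equation
(`scipy.linalg.solve_continuous_lyapunov`; solutions symmetrized and
validated against the residual), gradient `∇J = 2(RwF − B2ᵀP)W` with W the
closed-loop controllability Gramian, and the trace identity
`trace(B1ᵀPB1) = trace((I+FᵀF)W)` as a cross-check. A closed loop is
accepted as stable when its spectral abscissa is below −1e−9; marginally
stable loops (e.g. F = 0 on any connected graph) are rejected because the
H2 integral diverges.

Because L is symmetric PSD and all weights are identity, the γ=0 problem
has the closed form `F* = −L + (L²+I)^{1/2}`, `J* = Σ(√(λ²+1) − λ)`; this
is simultaneously the ADMM initializer and an analytic oracle for the
solver (the closed loop `−(L²+I)^{1/2}` has eigenvalues ≤ −1, so the
initializer stabilizes any graph, including disconnected ones; no
component filtering is needed anywhere).

The sparsity-promoting solve is ADMM on `J(F) + γ·card(G)` s.t. `F = G`
with penalty ρ = 100, stopping when `‖F−G‖_F ≤ 1e−4·N`, capped at 100
iterations. The F-step minimizes `J(F) + (ρ/2)‖F − (G − Λ/ρ)‖²` by
Anderson–Moore: with Gramians frozen, stationarity is linear in F
(`F(2W+ρI) = 2PW + ρU`), and an Armijo backtracking line search along the
update direction keeps the iterate stabilizing and the objective
decreasing (inner tolerance 1e−6, 30 iterations). The G-step is the exact
proximal operator of the cardinality penalty — hard thresholding at
`√(2γ/ρ)`. The final pattern is polished by projected gradient descent
(gradient masked to the pattern, adaptive step with backtracking,
tolerance 1e−7); if the thresholded iterate does not stabilize, diagonal
loading is tried before declaring the pattern infeasible. Channels are
counted as entries with `|F_ij| > 1e−10` — thresholding produces exact
zeros, the tolerance only guards polishing round-off. F is not constrained
to be symmetric, and diagonal entries count toward card(F) like any other.

γ homotopy matters. The objective is nonconvex, and the solution at each γ
seeds the next; the default path is the 7-point log grid 1e−4…1e−1.
Solving a requested γ in isolation (or along a very coarse path) lands in
different local minima — on random networks it can jump straight to
near-diagonal patterns at γ = 1e−2, roughly halving their apparent total
cost — so the sweep always traverses the full homotopy grid and reports
the requested γ values from it. The three-regime structure of the results
(below) is stable under the default path at both N = 100 and N = 50.

## The sweep and its summaries

`run_sweep` computes per network: Q (and optionally null-normalized Q),
degree statistics, driver count, and the homotopy solutions at the
requested γ values, emitting one row per (network, γ) with the accounting
invariant `total = J + γ·card` holding exactly by construction. Solver
failures are flagged rows, not fatal. All randomness is derived from the
single config seed via `SeedSequence` spawn keys, making tables
byte-identical across runs.

`regime_ordering` ranks τ classes by mean total cost per γ. Under the
study conditions the minimum flips: random (τ=0) at γ=1e−4, modular (τ=1)
at γ=1e−2, centralized (τ=10) at γ=1e−1. The same ordering holds in a
reduced 50-node/150-edge variant, which the test suite uses to keep the
default run short; the full-scale run lives in
`analysis/03_sparse_control_sweep.py`.

`correlate` reports Spearman rank correlations (the observed associations
are monotone but visibly nonlinear, so rank correlation is the natural
choice; no significance testing or multiplicity correction is attempted).
Degenerate (constant) columns are flagged undefined rather than silently
dropped.

## Scaled-down defaults

The full study is 100 networks per τ ∈ {0..10} with 1,000 nulls each.
Desk-scale defaults are 10 networks per τ and 100 nulls (configuration,
not code): the analysis scripts complete in ~10 CPU-minutes each and the
test suite in a few minutes, while every qualitative conclusion —
ensemble statistics, regime orderings, correlation signs — reproduces at
this scale. Sampling error of the ensemble means over 10 seeds is a few
percent (reported alongside the means in `analysis/01`).

## What the generator does and does not emulate

The synthetic ensembles reproduce the degree/modularity/centralization
spectrum the rewiring process explores — not real biological networks.
All graphs share one (N, E); conclusions about topology are therefore at
fixed size and density, and the Laplacian closed loop with identity
weights is the simplest possible control configuration. Passing tests show
the topology–cost trade-offs hold for these ensembles and this dynamics,
not that they transfer to directed, weighted, or differently sized
networks.

## Known limitations

* card-penalty ADMM is a local heuristic: returned patterns are polished
  local optima along the homotopy path, not certified global minima (on
  K2 the brute-force pattern optimum at γ=0.1 is sparser than the ADMM
  fixed point, a known property of hard-thresholding at fixed ρ).
* At the transition region (τ≈7–8) run-to-run topology variance is large;
  regime statements are made only for the three reference τ values.
* The Lyapunov solves are dense O(N³); the sweep is comfortable at
  N = 100 but not intended for N ≫ 10³.
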