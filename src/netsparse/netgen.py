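"""Network generation by heat-kernel adaptive rewiring.

Networks self-organize under an adaptive-rewiring rule driven by graph
diffusion: at each step a pivot node cuts the edge to the neighbor it
exchanges the least heat with and connects to the non-neighbor it exchanges
the most heat with, where heat flow is measured by the kernel
``h = exp(-tau * Lhat)`` of the symmetric degree-normalized Laplacian
``Lhat = I - D^{-1/2} A D^{-1/2}``.  A fraction of steps rewires uniformly
at random instead.  The diffusion scale ``tau`` selects the emergent
topology: ``tau = 0`` leaves the graph an Erdos-Renyi random graph,
intermediate ``tau`` grows modular community structure, and large ``tau``
concentrates edges on a few hubs (star-like centralization).

Graphs are :class:`networkx.Graph` instances with integer nodes
``0..n_nodes-1``; all operations preserve node count, edge count and
simplicity (no self-loops or parallel edges).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .exceptions import DegenerateGraphError

__all__ = [
    "RewiringConfig",
    "init_random_graph",
    "heat_kernel",
    "rewire_step",
    "generate_ensemble",
    "degree_preserving_null",
]

# Redrawing a pivot more than this many times per node means no node has both
# a neighbor and a non-neighbor, i.e. the graph is empty or complete.
_PIVOT_RETRY_FACTOR = 10


@dataclass
class RewiringConfig:
    """Parameters of one adaptive-rewiring run.

    Defaults are the study conditions: 100 nodes, 300 edges, 600 rewiring
    steps with 10% random rewiring, and 100 snapshots taken at constant rate.
    ``kernel_refresh`` recomputes the diffusion kernel every that many
    accepted steps (1 = after every step; the kernel depends on the current
    graph, so values > 1 trade fidelity for speed).
    """

    tau: float
    n_steps: int = 600
    p_random: float = 0.10
    n_samples: int = 100
    n_nodes: int = 100
    n_edges: int = 300
    seed: int | None = None
    kernel_refresh: int = 1

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError(f"tau must be nonnegative, got {self.tau}")
        if not 0.0 <= self.p_random <= 1.0:
            raise ValueError(f"p_random must lie in [0, 1], got {self.p_random}")
        if self.n_steps <= 0 or self.n_samples <= 0:
            raise ValueError("n_steps and n_samples must be positive")
        if self.n_samples > self.n_steps:
            raise ValueError(
                f"cannot take {self.n_samples} snapshots in {self.n_steps} steps"
            )
        max_edges = self.n_nodes * (self.n_nodes - 1) // 2
        if self.n_edges > max_edges:
            raise ValueError(
                f"{self.n_edges} edges exceed the maximum {max_edges} "
                f"for {self.n_nodes} nodes"
            )
        if self.kernel_refresh < 1:
            raise ValueError("kernel_refresh must be >= 1")


def init_random_graph(n_nodes: int, n_edges: int, rng: np.random.Generator) -> nx.Graph:
    """Erdos-Renyi G(n, m) start: ``n_edges`` distinct unordered pairs drawn
    uniformly without replacement.

    Raises ``ValueError`` if ``n_edges`` exceeds ``n_nodes*(n_nodes-1)/2``.
    """
    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_edges > max_edges:
        raise ValueError(
            f"{n_edges} edges exceed the maximum {max_edges} for {n_nodes} nodes"
        )
    # Sample edge indices in the upper triangle without replacement, then
    # decode index -> (i, j).  Exact uniform sampling over all edge sets.
    chosen = rng.choice(max_edges, size=n_edges, replace=False)
    g = nx.empty_graph(n_nodes)
    i_of, j_of = np.triu_indices(n_nodes, k=1)
    g.add_edges_from(zip(i_of[chosen].tolist(), j_of[chosen].tolist()))
    return g


def normalized_laplacian(graph: nx.Graph) -> np.ndarray:
    """Symmetric degree-normalized Laplacian ``I - D^{-1/2} A D^{-1/2}``.

    Rows and columns of isolated (degree-0) nodes are set to zero, so such
    nodes neither emit nor absorb heat.
    """
    n = graph.number_of_nodes()
    a = nx.to_numpy_array(graph, nodelist=range(n))
    deg = a.sum(axis=1)
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1e-300)), 0.0)
    lhat = -inv_sqrt[:, None] * a * inv_sqrt[None, :]
    np.fill_diagonal(lhat, np.where(deg > 0, 1.0, 0.0))
    return lhat


def heat_kernel(graph: nx.Graph, tau: float) -> np.ndarray:
    """Diffusion kernel ``h = exp(-tau * Lhat)`` (symmetric; identity at tau=0)."""
    if tau < 0:
        raise ValueError(f"tau must be nonnegative, got {tau}")
    n = graph.number_of_nodes()
    if tau == 0:
        return np.eye(n)
    lhat = normalized_laplacian(graph)
    # Lhat is symmetric: exponentiate through its eigendecomposition, which
    # is faster and better conditioned than a general expm at this size.
    w, v = np.linalg.eigh(lhat)
    h = (v * np.exp(-tau * w)) @ v.T
    return 0.5 * (h + h.T)


def _draw_pivot(graph: nx.Graph, rng: np.random.Generator) -> int:
    """A pivot must have at least one neighbor and one non-neighbor."""
    n = graph.number_of_nodes()
    for _ in range(_PIVOT_RETRY_FACTOR * n):
        i = int(rng.integers(n))
        if 0 < graph.degree(i) < n - 1:
            return i
    raise DegenerateGraphError(
        "no node with both a neighbor and a non-neighbor; graph is empty or complete"
    )


def _argmax_tie(values: np.ndarray, rng: np.random.Generator) -> int:
    """Index of the maximum; ties broken uniformly at random."""
    m = values.max()
    ties = np.flatnonzero(values >= m - 1e-12 * max(1.0, abs(m)))
    return int(ties[int(rng.integers(ties.size))])


def rewire_step(
    graph: nx.Graph,
    kernel: np.ndarray,
    p_random: float,
    rng: np.random.Generator,
    pivot: int | None = None,
) -> nx.Graph:
    """One adaptive-rewiring move, applied in place; returns the graph.

    A pivot ``i`` is drawn uniformly among eligible nodes (at least one
    neighbor and one non-neighbor; ineligible nodes are redrawn).  With
    probability ``p_random`` one of its edges is cut and one non-edge added
    uniformly at random; otherwise the neighbor ``j`` minimizing
    ``kernel[i, j]`` is cut and the non-neighbor ``k`` maximizing
    ``kernel[i, k]`` is connected, ties broken uniformly.  Edge count is
    conserved exactly.  ``pivot`` forces the pivot node (it must be
    eligible); it is mainly a test seam.
    """
    n = graph.number_of_nodes()
    if pivot is None:
        i = _draw_pivot(graph, rng)
    else:
        i = pivot
        if not 0 < graph.degree(i) < n - 1:
            raise DegenerateGraphError(f"pivot {i} has no neighbor or no non-neighbor")
    neighbors = np.fromiter(graph.neighbors(i), dtype=np.int64)
    mask = np.ones(n, dtype=bool)
    mask[i] = False
    mask[neighbors] = False
    non_neighbors = np.flatnonzero(mask)
    if rng.random() < p_random:
        j = int(neighbors[int(rng.integers(neighbors.size))])
        k = int(non_neighbors[int(rng.integers(non_neighbors.size))])
    else:
        j = int(neighbors[_argmax_tie(-kernel[i, neighbors], rng)])
        k = int(non_neighbors[_argmax_tie(kernel[i, non_neighbors], rng)])
    graph.remove_edge(i, j)
    graph.add_edge(i, k)
    return graph


def generate_ensemble(config: RewiringConfig) -> list[nx.Graph]:
    """Run one adaptive-rewiring trajectory and return its snapshots.

    Starting from an Erdos-Renyi graph, performs ``n_steps`` rewiring moves
    and snapshots the graph every ``n_steps // n_samples`` steps (constant
    rate), returning ``n_samples`` independent copies.  Bit-reproducible
    under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    g = init_random_graph(config.n_nodes, config.n_edges, rng)
    interval = config.n_steps // config.n_samples
    snapshots: list[nx.Graph] = []
    kernel = heat_kernel(g, config.tau)
    for step in range(1, config.n_steps + 1):
        rewire_step(g, kernel, config.p_random, rng)
        if step % config.kernel_refresh == 0 and config.tau > 0:
            kernel = heat_kernel(g, config.tau)
        if step % interval == 0 and len(snapshots) < config.n_samples:
            snapshots.append(g.copy())
    return snapshots


def degree_preserving_null(
    graph: nx.Graph,
    n_swap_attempts: int | None = None,
    rng: np.random.Generator | None = None,
) -> nx.Graph:
    """Degree-preserving randomization by double-edge swaps.

    Repeatedly picks two edges (a,b), (c,d) and rewires them to (a,d), (c,b)
    when that creates neither a self-loop nor a parallel edge; illegal swaps
    are skipped.  Defaults to ``10 * E`` attempts.  The degree sequence of
    the result is identical to the input's; a complete graph is returned
    unchanged because no legal swap exists.
    """
    if graph.number_of_edges() < 2:
        raise ValueError("need at least 2 edges for degree-preserving swaps")
    if rng is None:
        rng = np.random.default_rng()
    g = graph.copy()
    edges = [tuple(e) for e in g.edges()]
    m = len(edges)
    if n_swap_attempts is None:
        n_swap_attempts = 10 * m
    for _ in range(n_swap_attempts):
        ia, ib = rng.integers(m), rng.integers(m)
        if ia == ib:
            continue
        a, b = edges[ia]
        c, d = edges[ib]
        if rng.random() < 0.5:
            c, d = d, c
        # proposed: (a, d), (c, b)
        if a == d or c == b or g.has_edge(a, d) or g.has_edge(c, b):
            continue
        g.remove_edge(a, b)
        g.remove_edge(c, d)
        g.add_edge(a, d)
        g.add_edge(c, b)
        edges[ia] = (a, d)
        edges[ib] = (c, b)
    return g
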