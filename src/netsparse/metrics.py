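"""Topology metrics: degree statistics, Newman-Girvan modularity, null-model
normalization.

The degree distribution is summarized by its mean ``2E/N`` and its sample
standard deviation, the latter serving as a centralization measure: a large
spread means a few hubs hold most connections.  Community structure is
quantified by Newman-Girvan modularity

    Q = sum_c [ e_c / E - (d_c / 2E)^2 ]

(intra-community edge fraction minus its degree-based random expectation),
maximized over partitions by a seeded Leiden search.  Because even random
graphs show spurious modularity, Q can be normalized against degree-
preserving null models.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import leidenalg
import networkx as nx
import numpy as np

from .exceptions import UndefinedMetricError
from .netgen import degree_preserving_null

__all__ = [
    "DegreeSummary",
    "Partition",
    "degree_stats",
    "find_communities",
    "modularity",
    "normalized_modularity",
]


@dataclass(frozen=True)
class DegreeSummary:
    mean_degree: float  # 2E/N
    degree_std: float  # sample standard deviation (ddof=1)
    density: float  # 2E/(N^2 - N)


@dataclass(frozen=True)
class Partition:
    """Community assignment: ``labels[v]`` is the community of node ``v``,
    with community ids contiguous from 0."""

    labels: tuple[int, ...]

    @property
    def n_communities(self) -> int:
        return max(self.labels) + 1 if self.labels else 0

    @classmethod
    def from_labels(cls, raw: list[int] | np.ndarray) -> "Partition":
        # relabel to contiguous ids in order of first appearance
        seen: dict[int, int] = {}
        out = []
        for x in raw:
            x = int(x)
            if x not in seen:
                seen[x] = len(seen)
            out.append(seen[x])
        return cls(labels=tuple(out))

    def communities(self) -> list[set[int]]:
        groups: list[set[int]] = [set() for _ in range(self.n_communities)]
        for v, c in enumerate(self.labels):
            groups[c].add(v)
        return groups


def degree_stats(graph: nx.Graph) -> DegreeSummary:
    """Mean degree, sample standard deviation of the degree sequence, density."""
    n = graph.number_of_nodes()
    if n < 2:
        raise ValueError("degree statistics need at least 2 nodes")
    deg = np.array([d for _, d in graph.degree()], dtype=float)
    e = graph.number_of_edges()
    return DegreeSummary(
        mean_degree=2.0 * e / n,
        degree_std=float(deg.std(ddof=1)),
        density=2.0 * e / (n * n - n),
    )


def modularity(graph: nx.Graph, partition: Partition) -> float:
    """Newman-Girvan modularity Q of a partition.

    Raises :class:`UndefinedMetricError` on a graph with no edges (Q has a
    2E denominator).
    """
    if graph.number_of_edges() == 0:
        raise UndefinedMetricError("modularity is undefined for an edgeless graph")
    if len(partition.labels) != graph.number_of_nodes():
        raise ValueError("partition does not cover all nodes")
    return float(nx.community.modularity(graph, partition.communities()))


def find_communities(
    graph: nx.Graph,
    rng: np.random.Generator | int | None = None,
    n_restarts: int = 5,
) -> Partition:
    """Partition locally maximizing Newman-Girvan modularity.

    Runs the Leiden algorithm (modularity objective) ``n_restarts`` times
    with seeds drawn from ``rng`` and keeps the best-Q partition;
    deterministic for a given seed.  An edgeless graph gets the singleton
    partition (every node its own community).
    """
    n = graph.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    if graph.number_of_edges() == 0:
        return Partition.from_labels(list(range(n)))
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    g = ig.Graph(n=n, edges=[tuple(e) for e in graph.edges()])
    best: Partition | None = None
    best_q = -np.inf
    for _ in range(max(1, n_restarts)):
        seed = int(rng.integers(2**31 - 1))
        part = leidenalg.find_partition(
            g, leidenalg.ModularityVertexPartition, seed=seed, n_iterations=-1
        )
        cand = Partition.from_labels(part.membership)
        q = modularity(graph, cand)
        if q > best_q:
            best_q, best = q, cand
    assert best is not None
    return best


def normalized_modularity(
    graph: nx.Graph,
    partition: Partition,
    null_graphs: list[nx.Graph],
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Modularity normalized against degree-preserving null models.

    Each null graph is re-partitioned by :func:`find_communities` and the
    observed Q is compared with the null distribution.  Returns
    ``(Q_ratio, Q_zscore)`` where ``Q_ratio = Q / mean(Q_null)`` is the
    primary normalization and the z-score is secondary.  Requires at least
    10 nulls; raises :class:`UndefinedMetricError` if the null mean is not
    positive (the ratio loses meaning).
    """
    if len(null_graphs) < 10:
        raise ValueError(
            f"need at least 10 null graphs for normalization, got {len(null_graphs)}"
        )
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    q_obs = modularity(graph, partition)
    q_null = np.array(
        [modularity(g0, find_communities(g0, rng)) for g0 in null_graphs]
    )
    mean_null = float(q_null.mean())
    if mean_null <= 0:
        raise UndefinedMetricError("null-model mean modularity is not positive")
    sd_null = float(q_null.std(ddof=1))
    z = (q_obs - mean_null) / sd_null if sd_null > 0 else float("nan")
    return q_obs / mean_null, z


def make_nulls(
    graph: nx.Graph, n_nulls: int, rng: np.random.Generator | int | None = None
) -> list[nx.Graph]:
    """Convenience: ``n_nulls`` degree-preserving randomizations of ``graph``."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return [degree_preserving_null(graph, rng=rng) for _ in range(n_nulls)]
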