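"""Minimum driver nodes for undirected networks via the PBH test.

For an undirected (symmetric, unweighted) network, the
Popov-Belevitch-Hautus controllability test reduces the minimum number of
independent control inputs — driver nodes — to the maximum geometric
multiplicity of the adjacency eigenvalues.  Since the adjacency matrix is
symmetric, geometric and algebraic multiplicities coincide, so the count is
the largest cluster of (numerically) equal eigenvalues.

A random graph typically has all adjacency eigenvalues simple (one driver
node), a star K_{1,m} has eigenvalue 0 with multiplicity m-1, and highly
symmetric or hub-dominated graphs need many more drivers.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = ["DriverResult", "min_driver_nodes"]


@dataclass(frozen=True)
class DriverResult:
    n_driver: int
    eigenvalue_clusters: tuple[tuple[float, int], ...]  # (value, multiplicity)
    tol_used: float


def min_driver_nodes(graph: nx.Graph, tol: float | None = None) -> DriverResult:
    """Maximum geometric multiplicity of adjacency eigenvalues.

    Sorted eigenvalues are clustered greedily: a gap larger than ``tol``
    starts a new cluster.  The default ``tol = 1e-8 * N * max|lambda|``
    scales with the spectral radius; integer adjacency matrices have distinct
    eigenvalues separated by far more than this in double precision.
    """
    n = graph.number_of_nodes()
    if n < 1:
        raise ValueError("graph must have at least one node")
    a = nx.to_numpy_array(graph, nodelist=range(n))
    lam = np.linalg.eigvalsh(a)
    if tol is None:
        tol = 1e-8 * n * float(np.abs(lam).max(initial=0.0))
    clusters: list[list[float]] = [[float(lam[0])]]
    for x in lam[1:]:
        if float(x) - clusters[-1][-1] > tol:
            clusters.append([float(x)])
        else:
            clusters[-1].append(float(x))
    summary = tuple((float(np.mean(c)), len(c)) for c in clusters)
    n_driver = max(len(c) for c in clusters)
    return DriverResult(n_driver=n_driver, eigenvalue_clusters=summary, tol_used=tol)
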