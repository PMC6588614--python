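"""Graph and matrix I/O.

Graphs travel as two-column tab-separated edge lists: 0-based node ids, one
undirected edge per line with ``i < j``.  A header comment carries the node
count so isolated nodes survive the round trip.  Adjacency and gain matrices
can be exported in MatrixMarket coordinate format via :mod:`scipy.io`.
"""

from __future__ import annotations

import os

import networkx as nx
import numpy as np
import scipy.io
import scipy.sparse

__all__ = ["write_edgelist", "read_edgelist", "write_adjacency_mm", "write_gain_mm"]


def write_edgelist(graph: nx.Graph, path: str | os.PathLike) -> None:
    """Write ``graph`` as a sorted TSV edge list with an ``# n_nodes`` header."""
    with open(path, "w") as fh:
        fh.write(f"# n_nodes\t{graph.number_of_nodes()}\n")
        for i, j in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{i}\t{j}\n")


def read_edgelist(path: str | os.PathLike) -> nx.Graph:
    """Read a TSV edge list written by :func:`write_edgelist`.

    Files without the ``# n_nodes`` header are accepted; the node count is
    then ``max id + 1``.
    """
    n_nodes = None
    edges: list[tuple[int, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line.lstrip("#").split()
                if len(parts) == 2 and parts[0] == "n_nodes":
                    n_nodes = int(parts[1])
                continue
            i, j = (int(x) for x in line.split("\t"))
            if i == j:
                raise ValueError(f"self-loop {i}-{j} in edge list")
            edges.append((min(i, j), max(i, j)))
    if len(set(edges)) != len(edges):
        raise ValueError("duplicate edges in edge list")
    if n_nodes is None:
        n_nodes = max((j for _, j in edges), default=-1) + 1
    g = nx.empty_graph(n_nodes)
    g.add_edges_from(edges)
    return g


def write_adjacency_mm(graph: nx.Graph, path: str | os.PathLike) -> None:
    """Adjacency matrix in MatrixMarket coordinate format."""
    a = nx.to_scipy_sparse_array(graph, nodelist=range(graph.number_of_nodes()))
    scipy.io.mmwrite(os.fspath(path), scipy.sparse.coo_array(a))


def write_gain_mm(gain: np.ndarray, path: str | os.PathLike, tol: float = 0.0) -> None:
    """Feedback gain in MatrixMarket coordinate format (entries with |F_ij| > tol)."""
    f = np.where(np.abs(gain) > tol, gain, 0.0)
    scipy.io.mmwrite(os.fspath(path), scipy.sparse.coo_array(f))
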