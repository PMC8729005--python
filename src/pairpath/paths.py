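"""Support-graph construction and bounded simple-path enumeration.

Paths are *vertex-simple*: no node repeats.  A path is an ordered but not
directed node sequence, so each path is reported exactly once, oriented from
the query source to the query target, and the full listing is deterministic
(sorted by length, then lexicographically by node sequence).
"""

from __future__ import annotations

import math

import networkx as nx

from .errors import ValidationError
from .ggm import PartialCorrMatrix

#: Default |pi| threshold below which an entry is treated as a non-edge for
#: dense (e.g. inverse-Pearson) estimates.  Lasso estimates produce exact
#: zeros, so a threshold of 0.0 is appropriate there.
DEFAULT_ZERO_THRESHOLD = 0.0

NodePath = tuple[str, ...]


def support_graph(p: PartialCorrMatrix,
                  zero_threshold: float = DEFAULT_ZERO_THRESHOLD) -> nx.Graph:
    """Undirected graph with an edge wherever ``|pi_ij| > zero_threshold``.

    Edge weights carry the signed partial correlation.
    """
    if zero_threshold < 0:
        raise ValidationError("zero_threshold must be nonnegative")
    g = nx.Graph()
    g.add_nodes_from(p.labels)
    vals = p.values
    n = p.n
    for i in range(n):
        for j in range(i + 1, n):
            if abs(vals[i, j]) > zero_threshold:
                g.add_edge(p.labels[i], p.labels[j],
                           partial_correlation=float(vals[i, j]))
    return g


def path_length(path: NodePath) -> int:
    """Number of edges in a path."""
    return len(path) - 1


def enumerate_paths(g: nx.Graph, i: str, j: str, k: int) -> list[NodePath]:
    """All simple paths from ``i`` to ``j`` with at most ``k`` edges.

    Returned in deterministic order: by length, then lexicographic node
    sequence.  Each path appears once, oriented from ``i`` to ``j``.
    """
    if i == j:
        raise ValidationError(
            f"path enumeration requires distinct endpoints, got {i!r} twice")
    for node in (i, j):
        if node not in g:
            raise ValidationError(f"unknown node label {node!r}")
    if k < 1:
        raise ValidationError(f"path length cutoff must be >= 1, got {k}")
    paths = [tuple(p) for p in nx.all_simple_paths(g, i, j, cutoff=k)]
    paths.sort(key=lambda p: (len(p), p))
    return paths


def count_paths_complete_graph(n: int, k: int) -> int:
    """Number of simple i-j paths of length <= k in the complete graph K_n.

    A path of length ``m`` chooses an ordered sequence of ``m - 1`` interior
    nodes from the ``n - 2`` non-terminal nodes, giving
    ``sum_{m=1..k} (n-2)! / (n-1-m)!``.
    """
    if n < 2:
        raise ValidationError(f"need at least 2 nodes, got {n}")
    if k < 1:
        raise ValidationError(f"cutoff must be >= 1, got {k}")
    if k >= n:
        raise ValidationError(
            f"no simple path in a {n}-node graph has more than {n - 1} edges "
            f"(got cutoff {k})")
    return sum(math.perm(n - 2, m - 1) for m in range(1, k + 1))
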