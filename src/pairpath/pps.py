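"""Pair-path subscores: exact decomposition of a marginal correlation into
signed, determinant-weighted path contributions.

For a pair (i, j) and a simple path p connecting them:

* ``tau_p``   — product of partial correlations along the path's edges;
* ``gamma_p`` — ``tau_p * |A_{p*}| / sqrt(|A_{i*}| |A_{j*}|)``, where ``A``
  is the normalized precision, ``A_{p*}`` deletes every node of the path
  (terminals included) and ``A_{i*}`` deletes only node i.  Summed over all
  simple paths between i and j, the gammas reconstruct the marginal Pearson
  correlation exactly.
* ``s_p``     — the pair-path subscore ``|gamma_p| / sum_q |gamma_q|`` over
  the enumerated path set, a number in [0, 1]; scores sum to 1.

Two implementations coexist deliberately: a direct per-path route
(:func:`tau`, :func:`gamma`) and a vectorized plan
(:class:`PairDecompositionPlan`) used by the decomposition and the
simulation machinery.  The test suite cross-checks them against each other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import NoPathsError, ValidationError
from .ggm import PartialCorrMatrix, normalized_precision_values
from .paths import NodePath, enumerate_paths, support_graph

#: Below this total absolute contribution a pair is reported as having no
#: usable paths rather than risking division by ~0 in the normalization.
ZERO_TOTAL_TOLERANCE = 1e-300

#: |reconstructed correlation| below this, while individual contributions are
#: nonzero, is flagged as sign cancellation in output metadata.
CANCELLATION_TOLERANCE = 1e-12


def _path_key(path: NodePath) -> tuple:
    # deterministic tie-break: shortest first, then lexicographic nodes
    return (len(path), path)


def tau(p: PartialCorrMatrix, path: NodePath) -> float:
    """Product of partial correlations along the edges of ``path``."""
    if len(path) < 2:
        raise ValidationError("a path needs at least two nodes")
    if len(set(path)) != len(path):
        raise ValidationError(f"path repeats a node: {path}")
    out = 1.0
    for a, b in zip(path, path[1:]):
        pi = p.entry(a, b)
        if pi == 0.0:
            warnings.warn(
                f"path step ({a}, {b}) has zero partial correlation; the "
                "path is not in the support graph", stacklevel=2)
        out *= pi
    return out


def _det_removed(a: np.ndarray, removed: frozenset[int]) -> float:
    keep = [t for t in range(a.shape[0]) if t not in removed]
    if not keep:
        return 1.0  # determinant of the empty matrix
    sign, logdet = np.linalg.slogdet(a[np.ix_(keep, keep)])
    return float(sign * np.exp(logdet))


def gamma(p: PartialCorrMatrix, path: NodePath) -> float:
    """Signed contribution of one path to the terminal-pair correlation.

    Direct (non-vectorized) evaluation; the plan-based route must agree with
    this to numerical tolerance.
    """
    t = tau(p, path)
    a = normalized_precision_values(p.values)
    idx = [p.index_of(x) for x in path]
    i, j = idx[0], idx[-1]
    det_p = _det_removed(a, frozenset(idx))
    det_i = _det_removed(a, frozenset((i,)))
    det_j = _det_removed(a, frozenset((j,)))
    return t * det_p / np.sqrt(det_i * det_j)


class PairDecompositionPlan:
    """Precomputed structure for repeatedly decomposing one node pair.

    Built once from a path list, then evaluated against any partial-
    correlation array over the same labels.  Paths whose edges are absent in
    a particular matrix simply contribute gamma = 0, so a plan built on a
    superset support graph (e.g. the complete graph) is exact for every
    matrix — this is what makes the simulation loops cheap.

    Determinants of principal submatrices are deduplicated by removed-node
    set and evaluated in batches (grouped by size) via ``slogdet``.
    """

    def __init__(self, labels: tuple[str, ...], source: str, target: str,
                 paths: list[NodePath]):
        self.labels = tuple(labels)
        self.source = source
        self.target = target
        self.paths = sorted(paths, key=_path_key)
        index = {lab: t for t, lab in enumerate(self.labels)}
        self.source_idx = index[source]
        self.target_idx = index[target]
        n = len(self.labels)

        # unique removed-node sets, grouped by size for batched determinants
        path_idx = [tuple(index[x] for x in p) for p in self.paths]
        removed_sets: dict[frozenset[int], int] = {}
        self._set_of_path = np.empty(len(self.paths), dtype=np.intp)
        for t, idx in enumerate(path_idx):
            key = frozenset(idx)
            self._set_of_path[t] = removed_sets.setdefault(key, len(removed_sets))
        self._keep_groups: list[tuple[np.ndarray, np.ndarray]] = []
        by_size: dict[int, list[tuple[int, list[int]]]] = {}
        for key, sid in removed_sets.items():
            keep = [t for t in range(n) if t not in key]
            by_size.setdefault(len(keep), []).append((sid, keep))
        for size, group in by_size.items():
            sids = np.array([g[0] for g in group], dtype=np.intp)
            keeps = np.array([g[1] for g in group], dtype=np.intp)
            self._keep_groups.append((sids, keeps))
        self._n_sets = len(removed_sets)

        # per-length edge gather arrays for vectorized tau
        self._tau_groups: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
        by_len: dict[int, list[int]] = {}
        for t, idx in enumerate(path_idx):
            by_len.setdefault(len(idx), []).append(t)
        for m, rows in by_len.items():
            seq = np.array([path_idx[t] for t in rows], dtype=np.intp)
            self._tau_groups.append(
                (np.array(rows, dtype=np.intp), seq[:, :-1], seq[:, 1:]))

    def __len__(self) -> int:
        return len(self.paths)

    def taus(self, p_values: np.ndarray) -> np.ndarray:
        out = np.empty(len(self.paths))
        for rows, ka, kb in self._tau_groups:
            out[rows] = p_values[ka, kb].prod(axis=1)
        return out

    def gammas(self, p_values: np.ndarray) -> np.ndarray:
        """Signed contributions for every planned path, aligned with
        ``self.paths``."""
        if not self.paths:
            return np.empty(0)
        a = normalized_precision_values(p_values)
        dets = np.empty(self._n_sets)
        for sids, keeps in self._keep_groups:
            if keeps.shape[1] == 0:
                dets[sids] = 1.0
                continue
            sub = a[keeps[:, :, None], keeps[:, None, :]]
            sign, logdet = np.linalg.slogdet(sub)
            dets[sids] = sign * np.exp(logdet)
        det_i = _det_removed(a, frozenset((self.source_idx,)))
        det_j = _det_removed(a, frozenset((self.target_idx,)))
        return self.taus(p_values) * dets[self._set_of_path] / np.sqrt(det_i * det_j)

    def best_path(self, p_values: np.ndarray) -> tuple[NodePath, float, np.ndarray]:
        """(argmax path, its score, all gammas); raises if all gammas vanish.

        The argmax of the subscore does not depend on the normalization, so
        this works directly on |gamma| with the standard tie-break.
        """
        g = self.gammas(p_values)
        total = np.abs(g).sum()
        if not self.paths or total <= ZERO_TOTAL_TOLERANCE:
            raise NoPathsError(
                f"no paths with nonzero contribution between "
                f"{self.source!r} and {self.target!r}")
        order = sorted(range(len(g)),
                       key=lambda t: (-abs(g[t]),) + _path_key(self.paths[t]))
        best = order[0]
        return self.paths[best], float(abs(g[best]) / total), g


@dataclass(frozen=True)
class PathDecomposition:
    """Signed path contributions for one node pair at truncation ``k``.

    With full enumeration (k = n - 1) the gammas sum exactly to the
    marginal correlation of the pair.
    """

    pair: tuple[str, str]
    paths: tuple[NodePath, ...]
    taus: tuple[float, ...]
    gammas: tuple[float, ...]
    k: int

    @property
    def reconstructed_correlation(self) -> float:
        return float(sum(self.gammas))

    @property
    def total_abs_gamma(self) -> float:
        return float(sum(abs(g) for g in self.gammas))

    def __len__(self) -> int:
        return len(self.paths)


@dataclass(frozen=True)
class PPSTable:
    """Normalized pair-path subscores for one node pair.

    ``status`` is ``"ok"`` when scores exist, ``"no_paths"`` when the pair
    has no enumerated path with nonzero contribution (scores empty, never a
    division by zero).  ``cancellation`` flags a reconstructed correlation
    that is numerically zero while individual contributions are not.
    """

    pair: tuple[str, str]
    paths: tuple[NodePath, ...]
    scores: tuple[float, ...]
    k: int
    status: str
    cancellation: bool
    decomposition: PathDecomposition

    def __len__(self) -> int:
        return len(self.paths)

    @property
    def max_entry(self) -> tuple[NodePath, float]:
        if self.status != "ok":
            raise NoPathsError(
                f"no paths with nonzero contribution between "
                f"{self.pair[0]!r} and {self.pair[1]!r} (status "
                f"{self.status!r})")
        order = sorted(range(len(self.paths)),
                       key=lambda t: (-self.scores[t],) + _path_key(self.paths[t]))
        best = order[0]
        return self.paths[best], self.scores[best]


def plan_for_pair(p: PartialCorrMatrix, i: str, j: str, k: int,
                  graph=None) -> PairDecompositionPlan:
    """Build a decomposition plan from the support graph of ``p``."""
    if graph is None:
        graph = support_graph(p)
    paths = enumerate_paths(graph, i, j, k)
    return PairDecompositionPlan(p.labels, i, j, paths)


def decompose_correlation(p: PartialCorrMatrix, i: str, j: str, k: int,
                          graph=None) -> PathDecomposition:
    """Gamma for every simple path between ``i`` and ``j`` of length <= k.

    A disconnected pair yields an empty decomposition whose reconstructed
    correlation is 0.
    """
    if k is None:
        k = p.n - 1
    plan = plan_for_pair(p, i, j, k, graph=graph)
    if not plan.paths:
        return PathDecomposition((i, j), (), (), (), k)
    g = plan.gammas(p.values)
    t = plan.taus(p.values)
    return PathDecomposition((i, j), tuple(plan.paths),
                             tuple(float(x) for x in t),
                             tuple(float(x) for x in g), k)


def pps(p: PartialCorrMatrix, i: str, j: str, k: int, graph=None) -> PPSTable:
    """Pair-path subscores s_p = |gamma_p| / sum |gamma_q| at truncation k."""
    decomp = decompose_correlation(p, i, j, k, graph=graph)
    total = decomp.total_abs_gamma
    if len(decomp) == 0 or total <= ZERO_TOTAL_TOLERANCE:
        return PPSTable((i, j), (), (), k, "no_paths", False, decomp)
    scores = tuple(abs(g) / total for g in decomp.gammas)
    cancel = abs(decomp.reconstructed_correlation) < CANCELLATION_TOLERANCE
    return PPSTable((i, j), decomp.paths, scores, k, "ok", cancel, decomp)


def max_pps(p: PartialCorrMatrix, i: str, j: str, k: int,
            graph=None) -> tuple[NodePath, float]:
    """The highest-scoring path and its subscore; ties broken by shortest
    length then lexicographic node order."""
    return pps(p, i, j, k, graph=graph).max_entry
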