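"""Hypothesis-generation workflows: all-pairs max-subscore scans,
cross-condition ranking, per-node averages, edge-class summaries, and
nonparametric bootstrap confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EstimationError, NoPathsError, ValidationError
from .estimation import (EstimatedGGM, estimate_glasso,
                         estimate_inverse_pearson, select_lambda_cv)
from .ggm import PartialCorrMatrix
from .paths import support_graph
from .pps import pps


def _as_partial(model) -> tuple[PartialCorrMatrix, str]:
    if isinstance(model, EstimatedGGM):
        return model.partial, f"{model.method}(lambda={model.lam}, n={model.n})"
    if isinstance(model, PartialCorrMatrix):
        return model, "supplied"
    raise ValidationError(
        "expected an EstimatedGGM or PartialCorrMatrix, got "
        f"{type(model).__name__}")


@dataclass(frozen=True)
class MaxPPSScan:
    """One row per connected unordered pair: its best path and subscore."""

    table: pd.DataFrame = field(repr=False)
    k: int
    provenance: str
    n_disconnected: int

    def __len__(self) -> int:
        return len(self.table)

    def lookup(self, a: str, b: str) -> pd.Series:
        a, b = sorted((a, b))
        hit = self.table[(self.table.pair_a == a) & (self.table.pair_b == b)]
        if hit.empty:
            raise KeyError(f"pair ({a}, {b}) not in scan (disconnected?)")
        return hit.iloc[0]

    @property
    def labels(self) -> set[str]:
        return set(self.table.pair_a) | set(self.table.pair_b)


def max_pps_scan(model, k: int) -> MaxPPSScan:
    """Best path and subscore for every connected unordered pair.

    Pairs with no enumerated path of nonzero contribution within ``k`` are
    omitted; their count is reported on the result.
    """
    p, provenance = _as_partial(model)
    graph = support_graph(p)
    rows = []
    n_disconnected = 0
    for a_idx in range(p.n):
        for b_idx in range(a_idx + 1, p.n):
            a, b = sorted((p.labels[a_idx], p.labels[b_idx]))
            table = pps(p, a, b, k, graph=graph)
            if table.status != "ok":
                n_disconnected += 1
                continue
            path, score = table.max_entry
            rows.append({
                "pair_a": a, "pair_b": b,
                "best_path": "|".join(path),
                "best_path_len": len(path) - 1,
                "best_score": score,
                "n_paths": len(table),
                "adjacent": bool(graph.has_edge(a, b)),
                "k": k,
            })
    columns = ["pair_a", "pair_b", "best_path", "best_path_len",
               "best_score", "n_paths", "adjacent", "k"]
    df = pd.DataFrame(rows, columns=columns)
    df = df.sort_values(["pair_a", "pair_b"]).reset_index(drop=True)
    return MaxPPSScan(df, k, provenance, n_disconnected)


def condition_difference(scan_a: MaxPPSScan,
                         scan_b: MaxPPSScan) -> pd.DataFrame:
    """Pairs ranked by absolute difference in max subscore between two scans.

    A pair connected in only one condition contributes its score against 0
    and is flagged ``one_sided``.  Ties order lexicographically by pair.
    """
    if not (scan_a.labels & scan_b.labels):
        raise ValidationError("scans share no node labels")
    key = ["pair_a", "pair_b"]
    a = scan_a.table[key + ["best_score", "best_path"]].rename(
        columns={"best_score": "score_a", "best_path": "path_a"})
    b = scan_b.table[key + ["best_score", "best_path"]].rename(
        columns={"best_score": "score_b", "best_path": "path_b"})
    merged = a.merge(b, on=key, how="outer")
    merged["one_sided"] = merged.score_a.isna() | merged.score_b.isna()
    merged["score_a"] = merged.score_a.fillna(0.0)
    merged["score_b"] = merged.score_b.fillna(0.0)
    merged["abs_difference"] = (merged.score_a - merged.score_b).abs()
    merged = merged.sort_values(
        ["abs_difference", "pair_a", "pair_b"],
        ascending=[False, True, True]).reset_index(drop=True)
    return merged


@dataclass(frozen=True)
class NodeAverage:
    node: str
    value: float        # NaN when the node has no partners
    n_partners: int
    status: str         # "ok" | "isolated"
    k: int


def node_average_max_pps(scan: MaxPPSScan, node: str,
                         adjacent_only: bool = False) -> NodeAverage:
    """Mean of the best subscores over all partners of ``node`` in the scan.

    ``adjacent_only`` restricts partners to graph neighbors; the default
    counts every partner joined by >= 1 enumerated path within the scan's k.
    """
    t = scan.table
    mask = (t.pair_a == node) | (t.pair_b == node)
    if adjacent_only:
        mask &= t.adjacent
    sub = t[mask]
    if sub.empty:
        return NodeAverage(node, float("nan"), 0, "isolated", scan.k)
    return NodeAverage(node, float(sub.best_score.mean()), len(sub), "ok",
                       scan.k)


def edge_class_pps(model, k: int, class_map: dict[str, str]) -> pd.DataFrame:
    """Subscore of the direct edge for every within-class adjacent pair.

    One row per adjacent same-class pair; use :func:`summarize_edge_class`
    for per-class mean/SD.  Classes with no adjacent pairs yield no rows.
    """
    p, _ = _as_partial(model)
    graph = support_graph(p)
    rows = []
    for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
        ca, cb = class_map.get(a), class_map.get(b)
        if ca is None or cb is None or ca != cb:
            continue
        table = pps(p, a, b, k, graph=graph)
        edge_path = (a, b)
        try:
            idx = table.paths.index(edge_path)
        except ValueError:
            continue  # edge carries zero contribution
        rows.append({"pair_a": a, "pair_b": b, "node_class": ca,
                     "edge_pps": table.scores[idx], "k": k})
    return pd.DataFrame(rows,
                        columns=["pair_a", "pair_b", "node_class",
                                 "edge_pps", "k"])


def summarize_edge_class(edge_table: pd.DataFrame) -> pd.DataFrame:
    """Per-class mean, SD and count of direct-edge subscores."""
    if edge_table.empty:
        return pd.DataFrame(columns=["node_class", "mean", "sd", "count"])
    grouped = edge_table.groupby("node_class")["edge_pps"]
    out = grouped.agg(mean="mean", sd="std", count="count").reset_index()
    return out.sort_values("node_class").reset_index(drop=True)


@dataclass(frozen=True)
class BootstrapCI:
    statistic: str
    estimate: float
    lower: float
    upper: float
    replicates: int       # requested B
    n_missing: int        # replicates where the statistic was undefined
    seed: int
    level: float = 0.95


def _make_estimator(method: str, lam, cv_folds: int, seed: int,
                    refit_lambda: bool, full_data: pd.DataFrame):
    """Estimator closure for bootstrap replicates.  With the lasso and
    lam='cv', ``refit_lambda`` re-selects the penalty on each resample;
    otherwise the full-data penalty is frozen."""
    if method == "inverse-pearson":
        return lambda data: estimate_inverse_pearson(data)
    if method == "glasso":
        if lam == "cv" and not refit_lambda:
            lam_frozen = select_lambda_cv(full_data, folds=cv_folds,
                                          seed=seed)
            return lambda data: estimate_glasso(data, lam_frozen)
        if lam == "cv":
            return lambda data: estimate_glasso(data, "cv",
                                                cv_folds=cv_folds, seed=seed)
        return lambda data: estimate_glasso(data, float(lam))
    raise ValidationError(f"unknown estimator method {method!r}")


def bootstrap_ci(data: pd.DataFrame, statistic, b: int, seed: int = 0, *,
                 method: str = "glasso", lam="cv", cv_folds: int = 5,
                 refit_lambda: bool = True, level: float = 0.95,
                 label: str = "statistic") -> BootstrapCI:
    """Percentile bootstrap CI for a scalar derived from an estimated model.

    ``statistic`` is a callable ``EstimatedGGM -> float``.  Rows are
    resampled with replacement, the model re-estimated, the statistic
    recomputed; replicates on which it is undefined (e.g. the pair is
    disconnected) are recorded as missing and excluded from the percentiles.
    """
    if b < 2:
        raise ValidationError("need at least 2 bootstrap replicates")
    est = _make_estimator(method, lam, cv_folds, seed, refit_lambda, data)
    point = float(statistic(est(data)))
    rng = np.random.default_rng(seed)
    n = data.shape[0]
    values = []
    n_missing = 0
    for _ in range(b):
        idx = rng.integers(0, n, size=n)
        resample = data.iloc[idx].reset_index(drop=True)
        resample.index = [f"r{t}" for t in range(n)]
        try:
            values.append(float(statistic(est(resample))))
        except (NoPathsError, EstimationError):
            n_missing += 1
    if not values:
        raise EstimationError(
            "statistic undefined on every bootstrap replicate")
    alpha = 1.0 - level
    lower, upper = np.percentile(values,
                                 [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return BootstrapCI(label, point, float(lower), float(upper), b,
                       n_missing, seed, level)


def max_pps_statistic(a: str, b: str, k: int):
    """Statistic factory: the max subscore for a fixed pair at cutoff k."""
    def stat(model: EstimatedGGM) -> float:
        table = pps(model.partial, *sorted((a, b)), k)
        return table.max_entry[1]
    return stat
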