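"""Synthetic Gaussian graphical models and the two accuracy experiments:
max-path identification success rate vs sample size, and sensitivity of the
truncated subscore to the path-length cutoff.

The generator draws Erdos-Renyi edges (default probability 0.2) with edge
partial correlations uniform on (-1, 1) and rejects draws whose normalized
precision is not positive definite, so accepted models are valid Gaussian
models with unit-variance marginals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import EstimationError, NoPathsError, ValidationError
from .estimation import estimate_glasso, estimate_inverse_pearson
from .ggm import PartialCorrMatrix, correlation_from_partial
from .paths import enumerate_paths, support_graph
from .pps import PairDecompositionPlan, pps

EULER_MASCHERONI = 0.577


@dataclass(frozen=True)
class RandomGGMConfig:
    """Configuration of the random-model generator."""

    n_nodes: int
    edge_prob: float = 0.2
    partial_range: tuple[float, float] = (-1.0, 1.0)
    seed: int = 0
    max_attempts: int = 1000

    def __post_init__(self):
        if self.n_nodes < 2:
            raise ValidationError("need at least 2 nodes")
        if not 0 <= self.edge_prob <= 1:
            raise ValidationError("edge_prob must be in [0, 1]")
        lo, hi = self.partial_range
        if not (-1.0 <= lo < hi <= 1.0):
            raise ValidationError("partial_range must be within (-1, 1)")


def _node_labels(n: int) -> tuple[str, ...]:
    width = len(str(n))
    return tuple(f"x{t + 1:0{width}d}" for t in range(n))


def random_ggm(config: RandomGGMConfig) -> PartialCorrMatrix:
    """Draw a valid random model by rejection sampling.

    Edges are Bernoulli(edge_prob); edge partials uniform on the configured
    range; non-edges are exactly zero.  Draws are repeated until the
    normalized precision is positive definite, preserving the stated
    marginal distributions conditional on acceptance.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_nodes
    labels = _node_labels(n)
    iu = np.triu_indices(n, 1)
    lo, hi = config.partial_range
    for _ in range(config.max_attempts):
        edges = rng.random(len(iu[0])) < config.edge_prob
        partials = rng.uniform(lo, hi, size=len(iu[0])) * edges
        values = np.eye(n)
        values[iu] = partials
        values = values + np.triu(values, 1).T
        try:
            return PartialCorrMatrix(labels, values)
        except Exception:
            continue
    raise ValidationError(
        f"no positive-definite model found in {config.max_attempts} "
        "attempts; try a narrower partial_range or lower edge_prob")


def sample_gaussian(p: PartialCorrMatrix, n: int, seed) -> pd.DataFrame:
    """``n`` draws from N(0, C) where C is the model's correlation matrix,
    so every node is marginally N(0, 1).  ``seed`` may be an int or a
    numpy Generator."""
    if n < 1:
        raise ValidationError("need at least one sample")
    rng = np.random.default_rng(seed)
    cov = correlation_from_partial(p).values
    x = rng.multivariate_normal(np.zeros(p.n), cov, size=n, method="eigh")
    return pd.DataFrame(x, columns=list(p.labels),
                        index=[f"s{t + 1}" for t in range(n)])


# ---------------------------------------------------------------------------
# Erdos-Renyi expected-path-length guidance for choosing the cutoff K
# ---------------------------------------------------------------------------

def er_expected_path_length(p_nodes: int, mean_degree: float) -> float:
    """Expected path length (log p - gamma)/log D + 1/2 of an Erdos-Renyi
    network with ``p_nodes`` nodes and mean degree ``D`` (> 1)."""
    if p_nodes < 2:
        raise ValidationError("need at least 2 nodes")
    if mean_degree <= 1:
        raise ValidationError(
            f"mean degree must exceed 1, got {mean_degree}")
    return (math.log(p_nodes) - EULER_MASCHERONI) / math.log(mean_degree) + 0.5


def er_mean_degree_for_length(p_nodes: int, target_length: float) -> float:
    """Mean degree at which the expected path length equals ``target_length``
    (solved numerically from :func:`er_expected_path_length`)."""
    if target_length <= 0.5:
        raise ValidationError("expected path length is always > 1/2")
    return float(brentq(
        lambda d: er_expected_path_length(p_nodes, d) - target_length,
        1.0 + 1e-9, 1e9, xtol=1e-12))


# ---------------------------------------------------------------------------
# Experiment machinery
# ---------------------------------------------------------------------------

def connected_pairs(p: PartialCorrMatrix, k: int) -> list[tuple[str, str]]:
    """Unordered label pairs joined by at least one path of length <= k."""
    graph = support_graph(p)
    out = []
    for a_idx in range(p.n):
        for b_idx in range(a_idx + 1, p.n):
            a, b = p.labels[a_idx], p.labels[b_idx]
            if enumerate_paths(graph, a, b, k):
                out.append((a, b))
    return out


def _complete_plan(labels, a: str, b: str, k: int) -> PairDecompositionPlan:
    """Plan over the complete graph on ``labels``: exact for any estimate,
    because paths through absent edges contribute zero."""
    import networkx as nx

    from .paths import enumerate_paths as enum
    g = nx.complete_graph(list(labels))
    return PairDecompositionPlan(tuple(labels), a, b, enum(g, a, b, k))


def _make_estimator(tag: str, seed: int):
    if tag == "inverse-pearson":
        return lambda data: estimate_inverse_pearson(data)
    if tag == "glasso-cv":
        return lambda data: estimate_glasso(data, "cv", seed=seed)
    if tag.startswith("glasso:"):
        lam = float(tag.split(":", 1)[1])
        return lambda data: estimate_glasso(data, lam)
    raise ValidationError(
        f"unknown estimator tag {tag!r}; expected 'inverse-pearson', "
        "'glasso-cv', 'glasso:<lambda>' or 'truth'")


def _min_abs_partial(p: PartialCorrMatrix, path) -> float:
    return min(abs(p.entry(a, b)) for a, b in zip(path, path[1:]))


def success_rate_experiment(p_true: PartialCorrMatrix, n_grid, reps: int,
                            k: int, estimator: str, seed: int = 0,
                            pairs=None) -> pd.DataFrame:
    """Fraction of replicates on which the estimated highest-subscore path
    equals the true one, per pair and sample size.

    ``estimator`` is ``"truth"`` (oracle), ``"inverse-pearson"``,
    ``"glasso-cv"`` or ``"glasso:<lambda>"``.  Estimator failures are
    recorded in the ``failures`` column and excluded from the rate.  Output
    is tidy: one row per (pair, n), with the true path's length and smallest
    absolute partial for stratification.
    """
    if reps < 1:
        raise ValidationError("need at least one replicate")
    if pairs is None:
        pairs = connected_pairs(p_true, k)
    plans = {pair: _complete_plan(p_true.labels, *pair, k) for pair in pairs}
    truth = {}
    for pair, plan in plans.items():
        path, _, _ = plan.best_path(p_true.values)
        truth[pair] = path
    ss = np.random.SeedSequence(seed)
    rows = []
    oracle = estimator == "truth"
    est = None if oracle else _make_estimator(estimator, seed)
    for n in n_grid:
        successes = {pair: 0 for pair in pairs}
        failures = 0
        for child in ss.spawn(reps):
            rng = np.random.default_rng(child)
            if oracle:
                p_hat = p_true
            else:
                data = sample_gaussian(p_true, int(n), rng)
                try:
                    p_hat = est(data).partial
                except EstimationError:
                    failures += 1
                    continue
            for pair, plan in plans.items():
                try:
                    path, _, _ = plan.best_path(p_hat.values)
                except NoPathsError:
                    continue  # disconnected estimate: counted as a miss
                if path == truth[pair]:
                    successes[pair] += 1
        used = reps - failures
        for pair in pairs:
            rows.append({
                "pair_a": pair[0], "pair_b": pair[1], "n": int(n),
                "estimator": estimator, "k": k, "reps": used,
                "failures": failures, "successes": successes[pair],
                "success_rate": successes[pair] / used if used else np.nan,
                "true_path": "|".join(truth[pair]),
                "true_path_len": len(truth[pair]) - 1,
                "min_abs_partial": _min_abs_partial(p_true, truth[pair]),
            })
    return pd.DataFrame(rows)


def eligible_pairs_full_enumeration(p_true: PartialCorrMatrix,
                                    max_k: int) -> list[tuple[str, str]]:
    """Connected pairs all of whose simple paths in the true support graph
    have length <= max_k, so truncated and full enumeration coincide."""
    graph = support_graph(p_true)
    out = []
    for a_idx in range(p_true.n):
        for b_idx in range(a_idx + 1, p_true.n):
            a, b = p_true.labels[a_idx], p_true.labels[b_idx]
            all_paths = enumerate_paths(graph, a, b, p_true.n - 1)
            if all_paths and max(len(q) - 1 for q in all_paths) <= max_k:
                out.append((a, b))
    return out


def k_sensitivity_experiment(p_true: PartialCorrMatrix, n_grid, k_grid,
                             reps: int, seed: int = 0,
                             estimator: str = "inverse-pearson",
                             pairs=None) -> pd.DataFrame:
    """Percent error of the truncated estimate of the true max-path subscore,
    |s_hat^K(p_max) - s(p_max)| / s(p_max), per (pair, n, K).

    Pairs are restricted to those where full enumeration on the true support
    needs at most max(k_grid) edges, so the true subscore is exact.  Pairs
    whose true max subscore is zero are excluded (none exist for connected
    pairs, but the guard is explicit).
    """
    if reps < 1:
        raise ValidationError("need at least one replicate")
    k_grid = sorted(int(k) for k in k_grid)
    k_max = k_grid[-1]
    if pairs is None:
        pairs = eligible_pairs_full_enumeration(p_true, k_max)
    if not pairs:
        raise ValidationError(
            "no pairs with full enumeration within max(k_grid); "
            "supply pairs explicitly or raise the cutoff")
    graph = support_graph(p_true)
    plans, truth = {}, {}
    for pair in pairs:
        table = pps(p_true, *pair, k=p_true.n - 1, graph=graph)
        if table.status != "ok":
            continue
        path, score = table.max_entry
        plan = _complete_plan(p_true.labels, *pair, k_max)
        try:
            target = plan.paths.index(path)
        except ValueError:  # true path longer than k_max: ineligible
            continue
        plans[pair] = plan
        truth[pair] = (path, score, target)
    est = _make_estimator(estimator, seed) if estimator != "truth" else None
    lengths = {pair: np.array([len(q) - 1 for q in plan.paths])
               for pair, plan in plans.items()}
    ss = np.random.SeedSequence(seed)
    errors = {(pair, int(n), k): [] for pair in plans for n in n_grid
              for k in k_grid}
    for n in n_grid:
        for child in ss.spawn(reps):
            rng = np.random.default_rng(child)
            if est is None:
                p_hat = p_true
            else:
                data = sample_gaussian(p_true, int(n), rng)
                try:
                    p_hat = est(data).partial
                except EstimationError:
                    continue
            for pair, plan in plans.items():
                path, s_true, target = truth[pair]
                g = np.abs(plan.gammas(p_hat.values))
                for k in k_grid:
                    denom = g[lengths[pair] <= k].sum()
                    if len(path) - 1 > k or denom <= 0:
                        s_hat = 0.0
                    else:
                        s_hat = g[target] / denom
                    errors[(pair, int(n), k)].append(
                        abs(s_hat - s_true) / s_true)
    rows = []
    for (pair, n, k), errs in errors.items():
        errs = np.asarray(errs)
        rows.append({
            "pair_a": pair[0], "pair_b": pair[1], "n": n, "k": k,
            "estimator": estimator, "reps": len(errs),
            "mean_error": float(errs.mean()) if len(errs) else np.nan,
            "sd_error": float(errs.std(ddof=1)) if len(errs) > 1 else np.nan,
            "median_error": float(np.median(errs)) if len(errs) else np.nan,
            "true_path_len": len(truth[pair][0]) - 1,
            "true_max_pps": truth[pair][1],
        })
    return pd.DataFrame(rows)
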