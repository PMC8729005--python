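"""Estimation of the partial-correlation matrix from sample data.

Two routes: direct inversion of the sample Pearson correlation (dense,
requires n > p) and the graphical lasso (sparse, L1-penalized precision
estimation) with an optional cross-validated penalty.  Data matrices are
pandas DataFrames: one row per sample, one column per feature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.covariance import GraphicalLasso
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import KFold

from .errors import EstimationError, SingularMatrixError, ValidationError
from .ggm import (CorrMatrix, PartialCorrMatrix, partial_from_correlation,
                  partial_from_precision)

DEFAULT_CV_FOLDS = 5
DEFAULT_GRID_SIZE = 30
DEFAULT_GRID_RANGE = (1e-3, 1.0)  # scaled by max |off-diagonal covariance|


@dataclass(frozen=True)
class EstimatedGGM:
    """An estimated model: partial correlations plus estimation provenance."""

    partial: PartialCorrMatrix
    method: str            # "inverse-pearson" | "glasso"
    lam: float | None      # penalty used (None for inverse-pearson)
    n: int                 # samples used

    @property
    def labels(self) -> tuple[str, ...]:
        return self.partial.labels


def check_data(data: pd.DataFrame) -> pd.DataFrame:
    """Validate a samples x features table: numeric, complete, n >= 3,
    unique feature names."""
    if not isinstance(data, pd.DataFrame):
        raise ValidationError("data must be a pandas DataFrame")
    if data.columns.duplicated().any():
        dupes = sorted(set(data.columns[data.columns.duplicated()]))
        raise ValidationError(f"duplicate feature names: {dupes}")
    if data.shape[0] < 3:
        raise ValidationError(f"need at least 3 samples, got {data.shape[0]}")
    numeric = data.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = numeric.isna().any(axis=1)
        rows = list(data.index[bad][:5])
        raise ValidationError(
            f"missing or non-numeric values in rows {rows}")
    return numeric.astype(float)


def standardize(data: pd.DataFrame) -> pd.DataFrame:
    """Center each feature and scale to unit (ddof=1) variance."""
    centered = data - data.mean(axis=0)
    sd = centered.std(axis=0, ddof=1)
    zero = sd < 1e-12
    if zero.any():
        warnings.warn(
            f"features with (near-)zero variance left unscaled: "
            f"{list(sd.index[zero])}", stacklevel=2)
        sd = sd.where(~zero, 1.0)
    return centered / sd


def adjust_covariates(data: pd.DataFrame,
                      covariates: pd.DataFrame) -> pd.DataFrame:
    """Residualize every feature on the covariates (with intercept), then
    center and scale to unit variance.

    Features that are numerically explained by the covariates come back as
    zero vectors and are flagged with a warning.
    """
    data = check_data(data)
    if set(data.index) != set(covariates.index):
        raise ValidationError("data and covariate sample ids do not match")
    covariates = covariates.loc[data.index]
    constant = covariates.std(axis=0, ddof=1) < 1e-12
    if constant.any():
        warnings.warn(
            f"constant covariate columns dropped (intercept already "
            f"included): {list(covariates.columns[constant])}", stacklevel=2)
        covariates = covariates.loc[:, ~constant]
    x = np.column_stack(
        [np.ones(len(data)), np.asarray(covariates, dtype=float)])
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify columns that add no rank beyond their predecessors
        collinear = []
        for col in range(1, x.shape[1]):
            if np.linalg.matrix_rank(x[:, :col + 1]) == np.linalg.matrix_rank(x[:, :col]):
                collinear.append(str(covariates.columns[col - 1]))
        raise ValidationError(
            f"covariate matrix is rank deficient; collinear columns: "
            f"{collinear}")
    y = data.to_numpy()
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = pd.DataFrame(y - x @ beta, index=data.index,
                         columns=data.columns)
    return standardize(resid)


def estimate_inverse_pearson(data: pd.DataFrame) -> EstimatedGGM:
    """Partial correlations from inverting the sample Pearson correlation.

    Only valid when n > p; refuses otherwise and points to the lasso.
    """
    data = check_data(data)
    n, p = data.shape
    if n <= p:
        raise EstimationError(
            f"inverse-Pearson estimation requires n > p (got n={n}, p={p}); "
            "use estimate_glasso instead")
    c = np.corrcoef(data.to_numpy(), rowvar=False)
    if not np.all(np.isfinite(c)):
        raise EstimationError(
            "sample correlation matrix contains non-finite entries "
            "(constant feature?)")
    try:
        partial = partial_from_correlation(
            CorrMatrix(tuple(map(str, data.columns)), np.clip(c, -1.0, 1.0)))
    except SingularMatrixError as err:
        raise EstimationError(
            f"sample correlation matrix is not invertible: {err}") from err
    return EstimatedGGM(partial, "inverse-pearson", None, n)


def _fit_glasso(x: np.ndarray, lam: float, max_iter: int = 200) -> np.ndarray:
    """Fit the graphical lasso on standardized data; return the precision."""
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            model = GraphicalLasso(alpha=lam, max_iter=max_iter,
                                   assume_centered=True).fit(x)
        except ConvergenceWarning as warn:
            raise EstimationError(
                f"graphical lasso did not converge: {warn}", lam=lam,
                n_iter=max_iter) from warn
        except FloatingPointError as err:
            raise EstimationError(
                f"graphical lasso failed numerically: {err}", lam=lam) from err
    return model.precision_


def estimate_glasso(data: pd.DataFrame, lam: float | str = "cv", *,
                    cv_folds: int = DEFAULT_CV_FOLDS, grid=None,
                    seed: int = 0, max_iter: int = 200) -> EstimatedGGM:
    """Sparse partial correlations via L1-penalized precision estimation.

    Features are standardized first so the penalty is scale-free.  Exact
    zeros in the penalized precision are preserved in the partial matrix.
    ``lam="cv"`` selects the penalty with :func:`select_lambda_cv`.
    """
    data = check_data(data)
    z = standardize(data).to_numpy()
    if lam == "cv":
        lam = select_lambda_cv(data, folds=cv_folds, grid=grid, seed=seed,
                               max_iter=max_iter)
    lam = float(lam)
    if lam < 0:
        raise ValidationError(f"penalty must be nonnegative, got {lam}")
    precision = _fit_glasso(z, lam, max_iter=max_iter)
    partial = partial_from_precision(tuple(map(str, data.columns)), precision)
    return EstimatedGGM(partial, "glasso", lam, data.shape[0])


def default_lambda_grid(data: pd.DataFrame,
                        size: int = DEFAULT_GRID_SIZE) -> np.ndarray:
    """Log-spaced grid scaled to the largest off-diagonal sample covariance
    of the standardized features."""
    z = standardize(check_data(data)).to_numpy()
    cov = np.cov(z, rowvar=False)
    scale = float(np.abs(cov - np.diag(np.diag(cov))).max())
    if scale <= 0:
        scale = 1.0
    lo, hi = DEFAULT_GRID_RANGE
    return scale * np.logspace(np.log10(lo), np.log10(hi), size)


def _gaussian_holdout_loglik(precision: np.ndarray,
                             s_test: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(precision)
    if sign <= 0:
        return -np.inf
    return float(logdet - np.trace(s_test @ precision))


def select_lambda_cv(data: pd.DataFrame, folds: int = DEFAULT_CV_FOLDS,
                     grid=None, seed: int = 0,
                     max_iter: int = 200) -> float:
    """Penalty maximizing mean held-out Gaussian log-likelihood over folds.

    Fold assignment is deterministic in ``seed``.  Ties (and the argmax
    itself) resolve to the smallest maximizing penalty.
    """
    data = check_data(data)
    if folds < 2:
        raise ValidationError(f"need at least 2 folds, got {folds}")
    n = data.shape[0]
    if n // folds < 2:
        raise ValidationError(
            f"{n} samples is too few for {folds} folds (need >= 2 per fold)")
    if grid is None:
        grid = default_lambda_grid(data)
    grid = np.sort(np.asarray(grid, dtype=float))
    if len(grid) == 1:
        return float(grid[0])
    z = standardize(data).to_numpy()
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = np.zeros(len(grid))
    counts = np.zeros(len(grid))
    for train, test in kf.split(z):
        z_tr = z[train] - z[train].mean(axis=0)
        z_te = z[test] - z[test].mean(axis=0)
        s_test = (z_te.T @ z_te) / len(test)
        for g, lam in enumerate(grid):
            try:
                precision = _fit_glasso(z_tr, float(lam), max_iter=max_iter)
            except EstimationError:
                continue
            scores[g] += _gaussian_holdout_loglik(precision, s_test)
            counts[g] += 1
    valid = counts == counts.max()
    if counts.max() == 0:
        raise EstimationError("graphical lasso failed on every fold/penalty")
    mean_scores = np.where(valid, scores / np.maximum(counts, 1), -np.inf)
    return float(grid[int(np.argmax(mean_scores))])
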