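"""Exact linear-algebra relationships between precision, partial correlation,
and marginal correlation matrices of a Gaussian graphical model.

The central objects are labeled square matrices.  A partial-correlation
matrix ``P`` (unit diagonal, entries in [-1, 1]) defines a valid Gaussian
model iff its *normalized precision* ``A`` — the matrix with unit diagonal
and off-diagonal entries ``-pi_ij`` — is positive definite.  The marginal
(Pearson) correlation matrix is recovered by inverting ``A`` and rescaling
to unit diagonal, exactly as one passes from a covariance to a correlation
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidModelError, SingularMatrixError, ValidationError

# Minimum eigenvalue of the normalized precision above which a model is
# declared valid; separates genuine invalidity from floating-point noise.
PD_TOLERANCE = 1e-10

# Symmetry / unit-diagonal tolerance for user-supplied matrices.
SYMMETRY_TOLERANCE = 1e-8

# Condition-number ceiling for direct inversion of a correlation matrix.
CONDITION_LIMIT = 1e12


def _as_square(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValidationError(f"{name} must be square, got shape {arr.shape}")
    return arr


def _check_labels(labels, n: int) -> tuple[str, ...]:
    labels = tuple(str(x) for x in labels)
    if len(labels) != n:
        raise ValidationError(
            f"{len(labels)} labels supplied for a {n}x{n} matrix")
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValidationError(f"duplicate labels: {dupes}")
    return labels


def _check_symmetric(arr: np.ndarray, name: str,
                     tol: float = SYMMETRY_TOLERANCE) -> np.ndarray:
    delta = np.abs(arr - arr.T)
    if delta.size and delta.max() > tol:
        i, j = np.unravel_index(int(np.argmax(delta)), delta.shape)
        raise ValidationError(
            f"{name} is not symmetric: entry ({i},{j})={arr[i, j]!r} vs "
            f"({j},{i})={arr[j, i]!r}")
    return 0.5 * (arr + arr.T)


def _check_unit_diagonal(arr: np.ndarray, name: str,
                         tol: float = SYMMETRY_TOLERANCE) -> None:
    diag = np.diag(arr)
    bad = np.where(np.abs(diag - 1.0) > tol)[0]
    if bad.size:
        i = int(bad[0])
        raise ValidationError(
            f"{name} must have unit diagonal; entry ({i},{i}) = {diag[i]!r}")


@dataclass(frozen=True)
class LabeledMatrix:
    """A square matrix with node labels attached to rows and columns."""

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown node label {label!r}") from None

    def entry(self, a: str, b: str) -> float:
        return float(self.values[self.index_of(a), self.index_of(b)])

    def __eq__(self, other) -> bool:  # labels + values, not identity
        return (type(self) is type(other) and self.labels == other.labels
                and np.array_equal(self.values, other.values))


class PartialCorrMatrix(LabeledMatrix):
    """Symmetric unit-diagonal matrix of pairwise partial correlations.

    Validity (existence of an underlying Gaussian model) requires the
    normalized precision to be positive definite; this is checked eagerly
    unless ``require_valid=False``.
    """

    def __init__(self, labels, values, *, require_valid: bool = True):
        arr = _as_square(values, "partial correlation matrix")
        labels = _check_labels(labels, arr.shape[0])
        arr = _check_symmetric(arr, "partial correlation matrix")
        _check_unit_diagonal(arr, "partial correlation matrix")
        off = np.abs(arr - np.eye(arr.shape[0]))
        if off.size and off.max() > 1.0 + SYMMETRY_TOLERANCE:
            i, j = np.unravel_index(int(np.argmax(off)), off.shape)
            raise ValidationError(
                f"|partial correlation| > 1 at ({labels[i]}, {labels[j]}): "
                f"{arr[i, j]!r}")
        np.fill_diagonal(arr, 1.0)
        arr.setflags(write=False)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "values", arr)
        if require_valid:
            self.check_valid()

    def check_valid(self) -> float:
        """Return the minimum eigenvalue of A, raising if not PD."""
        a = normalized_precision_values(self.values)
        min_eig = float(np.linalg.eigvalsh(a).min())
        if min_eig <= PD_TOLERANCE:
            raise InvalidModelError(
                "partial correlation matrix does not define a valid Gaussian "
                f"model: min eigenvalue of normalized precision = {min_eig:g}",
                min_eigenvalue=min_eig)
        return min_eig


class NormalizedPrecision(LabeledMatrix):
    """Unit-diagonal matrix with off-diagonals equal to minus the partials."""

    def __init__(self, labels, values):
        arr = _as_square(values, "normalized precision")
        labels = _check_labels(labels, arr.shape[0])
        arr = _check_symmetric(arr, "normalized precision")
        _check_unit_diagonal(arr, "normalized precision")
        np.fill_diagonal(arr, 1.0)
        arr.setflags(write=False)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "values", arr)


class CorrMatrix(LabeledMatrix):
    """Symmetric unit-diagonal Pearson correlation matrix."""

    def __init__(self, labels, values):
        arr = _as_square(values, "correlation matrix")
        labels = _check_labels(labels, arr.shape[0])
        arr = _check_symmetric(arr, "correlation matrix")
        _check_unit_diagonal(arr, "correlation matrix")
        if np.abs(arr).max() > 1.0 + SYMMETRY_TOLERANCE:
            raise ValidationError("correlation entries must lie in [-1, 1]")
        np.fill_diagonal(arr, 1.0)
        arr.setflags(write=False)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "values", arr)


def normalized_precision_values(p_values: np.ndarray) -> np.ndarray:
    """Flip off-diagonal signs of a partial-correlation array (plain ndarray)."""
    a = -np.asarray(p_values, dtype=float).copy()
    np.fill_diagonal(a, 1.0)
    return a


def build_normalized_precision(p: PartialCorrMatrix) -> NormalizedPrecision:
    """a_ij = -pi_ij off-diagonal, a_ii = 1; labels preserved."""
    return NormalizedPrecision(p.labels, normalized_precision_values(p.values))


def _symmetric_inverse(arr: np.ndarray) -> np.ndarray:
    # average with the transpose so float drift never feeds asymmetry
    # into downstream path decompositions
    inv = np.linalg.inv(arr)
    return 0.5 * (inv + inv.T)


def correlation_from_partial(p: PartialCorrMatrix) -> CorrMatrix:
    """Marginal correlation matrix C = D^-1 A^-1 D^-1 of a valid model."""
    p.check_valid()
    a = normalized_precision_values(p.values)
    a_inv = _symmetric_inverse(a)
    d = np.sqrt(np.diag(a_inv))
    c = a_inv / np.outer(d, d)
    np.fill_diagonal(c, 1.0)
    return CorrMatrix(p.labels, c)


def partial_from_correlation(c: CorrMatrix) -> PartialCorrMatrix:
    """Invert a correlation matrix and normalize into partial correlations.

    Round-trips with :func:`correlation_from_partial` to numerical tolerance.
    """
    cond = float(np.linalg.cond(c.values))
    if not np.isfinite(cond) or cond > CONDITION_LIMIT:
        raise SingularMatrixError(
            f"correlation matrix is singular or near-singular (condition "
            f"number {cond:g}); use a regularized estimator such as the "
            "graphical lasso", condition_number=cond)
    omega = _symmetric_inverse(c.values)
    return partial_from_precision(c.labels, omega)


def partial_from_precision(labels, omega) -> PartialCorrMatrix:
    """pi_ij = -omega_ij / sqrt(omega_ii * omega_jj), unit diagonal."""
    omega = _as_square(omega, "precision matrix")
    omega = _check_symmetric(omega, "precision matrix")
    diag = np.diag(omega)
    if np.any(diag <= 0):
        raise InvalidModelError(
            "precision matrix has a non-positive diagonal entry; not "
            "positive definite")
    min_eig = float(np.linalg.eigvalsh(omega).min())
    if min_eig <= PD_TOLERANCE:
        raise InvalidModelError(
            f"precision matrix is not positive definite (min eigenvalue "
            f"{min_eig:g})", min_eigenvalue=min_eig)
    d = np.sqrt(diag)
    p = -omega / np.outer(d, d)
    np.fill_diagonal(p, 1.0)
    return PartialCorrMatrix(labels, p)
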