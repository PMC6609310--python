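"""Matrix-free voxelwise eigenvector centrality.

Eigenvector centrality (EC) of a network node is its entry in the dominant
eigenvector of the connection matrix: a voxel is central when its strongly
connected neighbours are themselves central.  For fMRI the connection matrix
is the ``N x N`` Pearson correlation matrix ``R`` of voxel time series,
shifted to ``R + 1`` so all entries are nonnegative and the Perron–Frobenius
theorem guarantees a unique nonnegative dominant eigenvector.

Forming ``R`` explicitly is infeasible at voxel resolution (``N^2`` memory),
but for rows ``Y`` that are demeaned and scaled to unit norm, ``R = Y Y^T``
and the power-iteration product factorizes::

    (R + 1) v  =  Y (Y^T v) + (sum v) * 1

which needs only ``O(N W)`` memory for a window of ``W`` time points.
Power iteration from a uniform nonnegative start vector converges inside the
Perron cone to the dominant eigenvector.

Zero-variance (degenerate) voxels cannot carry a correlation; they are kept
in place with centrality 0 so voxel indexing is stable across windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError, WindowTooShortError

__all__ = [
    "NormalizedSeries",
    "CentralityVector",
    "normalize_rows",
    "ecm_power_iteration",
    "scale_centrality",
]


@dataclass
class NormalizedSeries:
    """Rows demeaned and scaled to unit Euclidean norm; ``rows @ rows.T`` is ``R``."""

    rows: np.ndarray
    degenerate_rows: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def n_voxels(self) -> int:
        return self.rows.shape[0]


@dataclass
class CentralityVector:
    """Unit-norm nonnegative dominant-eigenvector estimate plus diagnostics."""

    values: np.ndarray
    eigenvalue: float
    iterations: int
    converged: bool


def normalize_rows(window: np.ndarray) -> NormalizedSeries:
    """Demean each row and scale it to unit Euclidean norm.

    Zero-variance rows are set to all-zero and recorded in
    ``degenerate_rows``.  Requires a window of at least 3 time points:
    with 2, every pairwise correlation is ±1 and centrality is vacuous.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 2:
        raise ValidationError("window must be a 2-D N x W array")
    if window.shape[1] < 3:
        raise WindowTooShortError(
            f"window length {window.shape[1]} < 3; correlations need at least 3 samples"
        )
    centered = window - window.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    scale = np.abs(window).max(axis=1)
    degenerate = norms <= 1e-10 * np.maximum(scale, 1.0)
    safe = np.where(degenerate, 1.0, norms)
    rows = centered / safe[:, np.newaxis]
    rows[degenerate] = 0.0
    return NormalizedSeries(rows=rows, degenerate_rows=np.flatnonzero(degenerate))


def ecm_power_iteration(
    s: NormalizedSeries,
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> CentralityVector:
    """Dominant eigenvector of the implicit ``R + 1`` matrix by power iteration.

    The product is evaluated matrix-free as ``rows @ (rows.T @ v) + sum(v)``,
    never materializing ``R``.  Iteration starts at the uniform vector
    ``1/sqrt(n)`` and stops when the Euclidean change between successive
    normalized iterates falls below ``tol``.  Degenerate rows get
    centrality 0 and do not participate in the implicit matrix.
    """
    if tol <= 0:
        raise ValidationError("tol must be positive")
    n_total = s.n_voxels
    good = np.ones(n_total, dtype=bool)
    good[s.degenerate_rows] = False
    rows = s.rows[good]
    n = rows.shape[0]
    if n < 2:
        raise ValidationError(f"need at least 2 non-degenerate voxels, got {n}")

    v = np.full(n, 1.0 / np.sqrt(n))
    eigenvalue = float(n)  # value for an exactly uniform fixed point
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        w = rows @ (rows.T @ v) + v.sum()
        eigenvalue = float(np.linalg.norm(w))
        if eigenvalue == 0.0:
            raise ValidationError("power iteration collapsed to the zero vector")
        v_new = w / eigenvalue
        if np.linalg.norm(v_new - v) < tol:
            v = v_new
            converged = True
            break
        v = v_new
    if not converged:
        warnings.warn(
            f"power iteration did not converge within {max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    # Perron vector is nonnegative; clip the roundoff dust and re-normalize.
    v = np.clip(v, 0.0, None)
    v /= np.linalg.norm(v)
    values = np.zeros(n_total)
    values[good] = v
    return CentralityVector(
        values=values, eigenvalue=eigenvalue, iterations=iterations, converged=converged
    )


def scale_centrality(v: CentralityVector | np.ndarray, target_mean: float = 4500.0) -> np.ndarray:
    """Rescale a centrality vector so its mean equals ``target_mean`` exactly.

    Positive rescaling preserves the ordering of voxels; the conventional
    target of 4500 puts dynamic EC maps on the intensity scale of the
    normalized fMRI data they came from.
    """
    values = v.values if isinstance(v, CentralityVector) else np.asarray(v, dtype=float)
    if target_mean <= 0:
        raise ValidationError("target_mean must be positive")
    mean = values.mean()
    if mean <= 0:
        raise ValidationError("cannot scale an all-zero centrality vector")
    return values * (target_mean / mean)
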