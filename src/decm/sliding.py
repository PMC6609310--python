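"""Sliding-window dynamic eigenvector centrality (dECM).

Given ``T`` volumes and a requested number ``M`` of centrality maps, a
window of ``W = T - M + 1`` volumes is slid over all ``M`` positions (step
of one TR) and eigenvector centrality is computed independently inside each
window.  ``M = 1`` reduces to the static ECM over the whole scan.  Subjects
scanned for different durations get different window lengths; the pipeline
records ``W`` per subject and exposes it as the scan-length covariate for
group statistics.

Each window is renormalized on its own (demean + unit norm within the
window) so that the implicit connection matrix is exactly that window's
correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .centrality import ecm_power_iteration, normalize_rows, scale_centrality
from .errors import ShapeError, ValidationError, WindowTooShortError
from .volumes import Mask3D, TimeSeriesMatrix, Volume4D, insert_map

__all__ = ["CentralitySeries", "sliding_window_ecm", "centrality_series_to_volume"]


@dataclass
class CentralitySeries:
    """``N x M`` matrix of scaled centralities, one column per window position."""

    values: np.ndarray
    window_length: int
    window_starts: np.ndarray
    tr: float = 1.0
    target_mean: float = 4500.0
    iterations: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    converged: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_maps(self) -> int:
        return self.values.shape[1]


def sliding_window_ecm(
    y: TimeSeriesMatrix,
    n_maps: int,
    tol: float = 1e-9,
    max_iter: int = 1000,
    target_mean: float = 4500.0,
) -> CentralitySeries:
    """Compute the time series of ``n_maps`` eigenvector centrality maps.

    Column ``j`` is the EC map of volumes ``[j, j + W)`` with
    ``W = T - n_maps + 1``; every column is independently power-iterated and
    scaled to mean ``target_mean``.
    """
    t = y.n_timepoints
    if n_maps < 1:
        raise ValidationError(f"number of maps must be >= 1, got {n_maps}")
    if n_maps > t - 2:
        raise WindowTooShortError(
            f"requesting {n_maps} maps from {t} volumes leaves a window of "
            f"{t - n_maps + 1} < 3; need T >= {n_maps + 2}"
        )
    w = t - n_maps + 1
    values = np.empty((y.n_voxels, n_maps))
    iters = np.empty(n_maps, dtype=int)
    conv = np.empty(n_maps, dtype=bool)
    for j in range(n_maps):
        ns = normalize_rows(y.values[:, j : j + w])
        cv = ecm_power_iteration(ns, tol=tol, max_iter=max_iter)
        values[:, j] = scale_centrality(cv, target_mean=target_mean)
        iters[j] = cv.iterations
        conv[j] = cv.converged
    return CentralitySeries(
        values=values,
        window_length=w,
        window_starts=np.arange(n_maps),
        tr=y.tr,
        target_mean=target_mean,
        iterations=iters,
        converged=conv,
    )


def centrality_series_to_volume(cs: CentralitySeries, mask: Mask3D) -> Volume4D:
    """Write the centrality series back onto the grid as an M-frame 4-D volume."""
    if cs.n_voxels != mask.count:
        raise ShapeError(
            f"centrality rows ({cs.n_voxels}) do not match mask count ({mask.count})"
        )
    return insert_map(cs.values, mask, fill=0.0, tr=cs.tr)
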