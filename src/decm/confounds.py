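"""Per-subject nuisance regression of motion parameters.

Head motion leaves residual signal in realigned fMRI even after spatial
correction.  The standard remedy used here is a per-subject GLM: each voxel's
time series is regressed on the rigid-body motion parameters and the fitted
motion contribution is subtracted.  The intercept is fit but *not* removed,
so every voxel keeps its temporal mean (the data arrive intensity-normalized
and Pearson correlation — hence centrality — is unaffected by the mean).
Confound columns are demeaned before fitting so the intercept equals the
voxel mean and the motion coefficients capture only fluctuations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateDesignError, InsufficientDofError, ShapeError
from .volumes import TimeSeriesMatrix

__all__ = ["ConfoundTable", "load_confounds", "regress_confounds"]


@dataclass
class ConfoundTable:
    """``T x P`` confound regressors (e.g. the 6 rigid-body motion parameters)."""

    values: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not self.labels:
            self.labels = [f"confound_{i}" for i in range(self.values.shape[1])]
        if len(self.labels) != self.values.shape[1]:
            raise ShapeError("label count does not match confound columns")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regressors(self) -> int:
        return self.values.shape[1]


def load_confounds(path: str | Path) -> ConfoundTable:
    """Read whitespace/tab-delimited motion parameters (T rows x P columns)."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    if df.iloc[0].apply(lambda v: isinstance(v, str)).any():
        df = pd.read_csv(path, sep=r"\s+", comment="#")
        return ConfoundTable(values=df.to_numpy(float), labels=[str(c) for c in df.columns])
    return ConfoundTable(values=df.to_numpy(float))


def _collinear_pair(c: np.ndarray, labels: list[str]) -> str:
    corr = np.corrcoef(c.T)
    np.fill_diagonal(corr, 0.0)
    i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
    return f"{labels[i]!r} and {labels[j]!r}"


def regress_confounds(y: TimeSeriesMatrix, c: ConfoundTable) -> TimeSeriesMatrix:
    """OLS-residualize every voxel time series on the demeaned confounds.

    Returns a new :class:`TimeSeriesMatrix` whose rows are orthogonal to the
    demeaned confound columns while keeping each voxel's temporal mean.
    The operation is idempotent.
    """
    t, p = c.n_timepoints, c.n_regressors
    if t != y.n_timepoints:
        raise ShapeError(
            f"confound rows ({t}) do not match series time points ({y.n_timepoints})"
        )
    if t <= p + 1:
        raise InsufficientDofError(
            f"need T > P+1 time points (T={t}, P={p}) for confound regression"
        )
    cd = c.values - c.values.mean(axis=0)
    # all-zero confounds: nothing to remove
    scale = np.abs(c.values).max() if c.values.size else 0.0
    if scale == 0.0 or np.abs(cd).max() <= 1e-15 * max(scale, 1.0):
        return TimeSeriesMatrix(values=y.values.copy(), voxel_index=y.voxel_index, tr=y.tr)
    keep = np.linalg.norm(cd, axis=0) > 1e-12 * max(scale, 1.0)
    cd_active = cd[:, keep]
    if np.linalg.matrix_rank(cd_active) < cd_active.shape[1]:
        labels = [lab for lab, k in zip(c.labels, keep) if k]
        raise DegenerateDesignError(
            f"confound matrix is rank deficient; most collinear columns: "
            f"{_collinear_pair(cd_active, labels)}"
        )
    beta, *_ = np.linalg.lstsq(cd_active, y.values.T, rcond=None)
    resid = y.values - (cd_active @ beta).T
    return TimeSeriesMatrix(values=resid, voxel_index=y.voxel_index, tr=y.tr)
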