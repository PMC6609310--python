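"""Group-level descriptive summaries of centrality dynamics.

Two products: per-subgroup mean EC maps (time-average per subject, then
arithmetic mean over the subgroup) and per-network group time-course curves
(winsorized mean across subjects, with the across-subject standard
deviation shrunk by a ribbon divisor for plotting).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dualregression import SubjectTimecourses
from .errors import ShapeError, ValidationError
from .sliding import CentralitySeries

__all__ = ["GroupCurves", "winsorized_mean", "group_mean_ecm", "network_curves"]


@dataclass
class GroupCurves:
    """Per-group K x M mean curves and dispersion ribbons."""

    means: dict[str, np.ndarray]
    ribbons: dict[str, np.ndarray]
    names: list[str]
    trim: float
    ribbon_scale: float


def winsorized_mean(values: np.ndarray | list[float], trim: float = 0.1) -> float:
    """Mean after replacing the ``floor(trim*n)`` most extreme values per tail.

    The replaced values are set to the nearest retained order statistic, so
    outliers are pulled in rather than dropped; ``trim=0`` (or ``trim*n < 1``)
    is the ordinary mean.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 1:
        raise ValidationError("winsorized_mean of an empty sequence")
    if not 0 <= trim < 0.5:
        raise ValidationError(f"trim must be in [0, 0.5), got {trim}")
    g = int(np.floor(trim * n))
    if g:
        x[:g] = x[g]
        x[n - g :] = x[n - g - 1]
    return float(x.mean())


def _winsorize_axis0(arr: np.ndarray, trim: float) -> np.ndarray:
    """Winsorized mean along axis 0 of an (n_subjects, ...) array."""
    x = np.sort(arr, axis=0)
    n = x.shape[0]
    g = int(np.floor(trim * n))
    if g:
        x[:g] = x[g : g + 1]
        x[n - g :] = x[n - g - 1 : n - g]
    return x.mean(axis=0)


def group_mean_ecm(
    series: list[CentralitySeries], groups: np.ndarray | list[str]
) -> dict[str, np.ndarray]:
    """Per-group mean EC map: time-average per subject, then mean over subjects."""
    groups = np.asarray(groups)
    if len(series) != groups.size:
        raise ShapeError("one group label per subject required")
    n = series[0].n_voxels
    if any(cs.n_voxels != n for cs in series):
        raise ShapeError("subjects have different voxel counts")
    subject_means = np.stack([cs.values.mean(axis=1) for cs in series])
    return {
        str(g): subject_means[groups == g].mean(axis=0) for g in np.unique(groups)
    }


def network_curves(
    timecourses: list[SubjectTimecourses],
    groups: np.ndarray | list[str],
    trim: float = 0.1,
    ribbon_scale: float = 5.0,
) -> GroupCurves:
    """Group mean network time courses with shrunk-s.d. ribbons.

    Per group, network and window position: winsorized mean across subjects
    and the across-subject standard deviation divided by ``ribbon_scale``.
    Groups with fewer than 2 subjects get a zero ribbon (with a warning).
    """
    if not 0 <= trim < 0.5:
        raise ValidationError(f"trim must be in [0, 0.5), got {trim}")
    groups = np.asarray(groups)
    if len(timecourses) != groups.size:
        raise ShapeError("one group label per subject required")
    shape = timecourses[0].values.shape
    if any(tc.values.shape != shape for tc in timecourses):
        raise ShapeError("subjects have different (K, M) time-course shapes")
    stack = np.stack([tc.values for tc in timecourses])  # (S, K, M)
    means: dict[str, np.ndarray] = {}
    ribbons: dict[str, np.ndarray] = {}
    for g in np.unique(groups):
        sub = stack[groups == g]
        means[str(g)] = _winsorize_axis0(sub.copy(), trim)
        if sub.shape[0] < 2:
            warnings.warn(
                f"group {g!r} has fewer than 2 subjects; ribbon set to 0",
                RuntimeWarning,
                stacklevel=2,
            )
            ribbons[str(g)] = np.zeros(shape)
        else:
            ribbons[str(g)] = sub.std(axis=0, ddof=1) / ribbon_scale
    return GroupCurves(
        means=means,
        ribbons=ribbons,
        names=list(timecourses[0].names),
        trim=trim,
        ribbon_scale=ribbon_scale,
    )
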