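"""Dual regression of centrality series onto spatial network templates.

Dual regression maps group-level resting-state network (RSN) templates to
subject-level quantities in two least-squares stages.  For a subject's data
``Y`` (here the ``N x M`` dynamic-EC series) and templates ``C`` (``N x K``
spatial Z-maps):

* **Stage 1 (spatial regression)** solves ``Y = C S + e`` for the ``K x M``
  network time courses ``S`` — one representative course per template, per
  subject.  Templates and data columns are spatially demeaned first.
* **Stage 2 (temporal regression)** solves ``Y^T = S^T D^T + e`` voxel by
  voxel (with an intercept) for the ``N x K`` correspondence maps ``D`` —
  how strongly each voxel's centrality course follows each network's course.

Stage-1 courses are variance-normalized by default so stage-2 coefficients
are comparable across subjects; disable with ``normalize=False`` where the
absolute centrality level matters (e.g. network-ordering summaries).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DegenerateDesignError, ShapeError, ValidationError
from .sliding import CentralitySeries
from .volumes import Mask3D, Volume4D, extract_timeseries

__all__ = [
    "TemplateSet",
    "SubjectTimecourses",
    "SubjectSpatialMaps",
    "templates_from_volume",
    "stage1_spatial_regression",
    "normalize_timecourses",
    "stage2_temporal_regression",
    "dual_regression",
    "make_network_mask",
]


@dataclass
class TemplateSet:
    """``N x K`` spatial Z-maps on the analysis-mask voxel set."""

    maps: np.ndarray
    names: list[str] = field(default_factory=list)
    zthreshold: float = 3.0

    def __post_init__(self) -> None:
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        if not self.names:
            self.names = [f"network_{i}" for i in range(self.maps.shape[1])]
        if len(self.names) != self.maps.shape[1]:
            raise ShapeError("template names do not match column count")
        if np.any(np.all(self.maps == 0, axis=0)):
            raise ValidationError("template set contains an all-zero column")

    @property
    def n_networks(self) -> int:
        return self.maps.shape[1]


@dataclass
class SubjectTimecourses:
    """``K x M`` per-network time courses from stage 1."""

    values: np.ndarray
    names: list[str] = field(default_factory=list)
    variance_normalized: bool = False


@dataclass
class SubjectSpatialMaps:
    """``N x K`` stage-2 regression coefficients (correspondence maps)."""

    values: np.ndarray
    names: list[str] = field(default_factory=list)


def templates_from_volume(
    vol: Volume4D, mask: Mask3D, names: list[str] | None = None, zthreshold: float = 3.0
) -> TemplateSet:
    """Build a :class:`TemplateSet` from a 4-D NIfTI with one Z-map per frame."""
    ts = extract_timeseries(vol, mask)
    return TemplateSet(maps=ts.values, names=names or [], zthreshold=zthreshold)


def load_template_names(path: str | Path) -> list[str]:
    """One network label per line."""
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def _check_collinear(x: np.ndarray, names: list[str], what: str) -> None:
    if np.linalg.matrix_rank(x) < x.shape[1]:
        corr = np.corrcoef(x.T)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise DegenerateDesignError(
            f"{what} are collinear; most correlated pair: {names[i]!r}, {names[j]!r}"
        )


def stage1_spatial_regression(cs: CentralitySeries, t: TemplateSet) -> SubjectTimecourses:
    """Regress each centrality map onto all templates jointly (spatial OLS).

    Both templates and the data columns are spatially demeaned, so the fit
    captures pattern correspondence rather than global intensity.
    """
    if cs.n_voxels != t.maps.shape[0]:
        raise ShapeError(
            f"centrality voxels ({cs.n_voxels}) do not match template voxels "
            f"({t.maps.shape[0]})"
        )
    if t.n_networks >= cs.n_voxels:
        raise ValidationError("need more voxels than templates")
    c = t.maps - t.maps.mean(axis=0)
    _check_collinear(c, t.names, "templates")
    y = cs.values - cs.values.mean(axis=0)
    s, *_ = np.linalg.lstsq(c, y, rcond=None)
    return SubjectTimecourses(values=s, names=list(t.names), variance_normalized=False)


def normalize_timecourses(s: SubjectTimecourses) -> SubjectTimecourses:
    """Scale each network time course to unit sample standard deviation."""
    sd = s.values.std(axis=1, ddof=1)
    bad = np.flatnonzero(sd <= 1e-300)
    if bad.size:
        names = [s.names[i] if s.names else str(i) for i in bad]
        raise ValidationError(f"zero-variance time course for network(s): {names}")
    return SubjectTimecourses(
        values=s.values / sd[:, np.newaxis], names=list(s.names), variance_normalized=True
    )


def stage2_temporal_regression(
    cs: CentralitySeries, s: SubjectTimecourses
) -> SubjectSpatialMaps:
    """Per-voxel multiple regression of the EC course on the network courses.

    An intercept absorbs each voxel's mean centrality; the ``K`` slope
    coefficients form the subject's correspondence maps.
    """
    k, m = s.values.shape
    if m != cs.n_maps:
        raise ShapeError(f"time courses ({m}) do not match window count ({cs.n_maps})")
    names = s.names or [f"network_{i}" for i in range(k)]
    _check_collinear(s.values.T, names, "time courses")
    x = np.column_stack([np.ones(m), s.values.T])
    beta, *_ = np.linalg.lstsq(x, cs.values.T, rcond=None)
    return SubjectSpatialMaps(values=beta[1:].T, names=list(names))


def dual_regression(
    cs: CentralitySeries, t: TemplateSet, normalize: bool = True
) -> tuple[SubjectTimecourses, SubjectSpatialMaps]:
    """Full two-stage dual regression for one subject.

    Returns the (unnormalized) stage-1 time courses and the stage-2 maps
    computed from their variance-normalized version (default).
    """
    s = stage1_spatial_regression(cs, t)
    s_used = normalize_timecourses(s) if normalize else s
    d = stage2_temporal_regression(cs, s_used)
    return s, d


def make_network_mask(t: TemplateSet, k: int, mask: Mask3D) -> Mask3D:
    """Voxels where template ``k`` exceeds its Z threshold, inside the analysis mask.

    Group statistics are restricted to each network's own support so that
    the test asks about EC variation *within* the network.
    """
    if not 0 <= k < t.n_networks:
        raise ValidationError(f"network index {k} out of range (K={t.n_networks})")
    supra = t.maps[:, k] > t.zthreshold
    flat = np.flatnonzero(mask.data.ravel(order="F"))
    grid = np.zeros(int(np.prod(mask.shape)), dtype=bool)
    grid[flat[supra]] = True
    out = Mask3D(data=grid.reshape(mask.shape, order="F"), affine=mask.affine)
    if out.count == 0:
        warnings.warn(
            f"network mask for {t.names[k]!r} is empty at Z > {t.zthreshold}",
            RuntimeWarning,
            stacklevel=2,
        )
    return out
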