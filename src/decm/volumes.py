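"""NIfTI image I/O, mask construction and grid <-> matrix conversion.

The carriers defined here are deliberately thin wrappers around numpy arrays:

* :class:`Volume4D` — an ``X x Y x Z x T`` grid with affine, voxel size and TR.
  3-D images are promoted to ``T = 1`` on read.
* :class:`Mask3D` — a binary grid plus its affine.
* :class:`TimeSeriesMatrix` — the ``N x T`` matrix of in-mask voxel time
  series, with the voxel <-> grid index map needed to write results back.

Masking follows the standard resting-state recipe: a gray-matter density
threshold per subject, a functional coverage mask from the map of temporal
minima (signal-dropout voxels have low minima), a group mask keeping voxels
present in at least a given fraction of subjects, and an intersection with
optional exclusion masks (e.g. cerebellum).

Row order of :class:`TimeSeriesMatrix` is fixed to Fortran grid traversal
(x fastest, then y, then z) so that maps are reproducible byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

from .errors import FormatError, ShapeError, ValidationError

__all__ = [
    "Volume4D",
    "Mask3D",
    "TimeSeriesMatrix",
    "read_volume4d",
    "write_volume4d",
    "read_mask",
    "write_mask",
    "build_graymatter_mask",
    "build_functional_mask",
    "combine_group_masks",
    "intersect_masks",
    "extract_timeseries",
    "insert_map",
]

#: Relative tolerance for affine agreement between grids.  Resampled files
#: commonly differ in last-digit header noise, so exact equality is too strict.
AFFINE_RTOL = 1e-4


def _check_affines(a: np.ndarray, b: np.ndarray) -> bool:
    scale = max(np.abs(a).max(), np.abs(b).max(), 1.0)
    return bool(np.all(np.abs(a - b) <= AFFINE_RTOL * scale))


@dataclass
class Volume4D:
    """A 4-D image grid (``X x Y x Z x T``) with spatial metadata."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tr: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:
            self.data = self.data[..., np.newaxis]
        if self.data.ndim != 4:
            raise FormatError(f"Volume4D requires 3-D or 4-D data, got {self.data.ndim}-D")
        if min(self.data.shape) < 1:
            raise ValidationError(f"degenerate grid shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ShapeError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValidationError("affine is not invertible")
        if any(v <= 0 for v in self.voxel_size):
            raise ValidationError(f"voxel size must be positive, got {self.voxel_size}")

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


@dataclass
class Mask3D:
    """A binary 3-D grid; ``count`` is the number of in-mask voxels."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim == 4 and arr.shape[3] == 1:
            arr = arr[..., 0]
        if arr.ndim != 3:
            raise FormatError(f"Mask3D requires a 3-D grid, got {arr.ndim}-D")
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValidationError("mask values must be 0 or 1")
        self.data = arr.astype(np.uint8)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def count(self) -> int:
        return int(self.data.sum())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class TimeSeriesMatrix:
    """``N x T`` in-mask voxel time series plus the voxel index map.

    ``voxel_index[i]`` gives the ``(x, y, z)`` grid coordinate of row ``i``;
    rows follow Fortran traversal of the grid (x fastest).
    """

    values: np.ndarray
    voxel_index: np.ndarray
    tr: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.voxel_index = np.asarray(self.voxel_index)
        if self.values.ndim != 2:
            raise ShapeError("values must be N x T")
        if self.voxel_index.shape != (self.values.shape[0], 3):
            raise ShapeError("voxel_index must be N x 3")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_volume4d(path: str | Path) -> Volume4D:
    """Read a NIfTI-1 file as a :class:`Volume4D` (3-D inputs promoted to T=1)."""
    path = Path(path)
    try:
        img = nib.load(path)
        data = np.asarray(img.get_fdata())
    except FileNotFoundError:
        raise
    except Exception as exc:  # corrupt / unreadable
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    if data.ndim not in (3, 4):
        raise FormatError(f"{path}: expected a 3-D or 4-D image, got {data.ndim} dimensions")
    zooms = img.header.get_zooms()
    voxel_size = tuple(float(z) for z in zooms[:3])
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return Volume4D(data=data, affine=np.asarray(img.affine), voxel_size=voxel_size, tr=tr)


def write_volume4d(vol: Volume4D, path: str | Path) -> Path:
    """Write a :class:`Volume4D` to NIfTI-1, carrying voxel size and TR."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float64), vol.affine)
    img.header.set_zooms(tuple(vol.voxel_size) + (float(vol.tr),))
    img.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(img, path)
    return path


def read_mask(path: str | Path) -> Mask3D:
    vol = read_volume4d(path)
    return Mask3D(data=(vol.data[..., 0] > 0.5), affine=vol.affine)


def write_mask(mask: Mask3D, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    nib.save(img, path)
    return path


# ---------------------------------------------------------------------------
# Mask construction
# ---------------------------------------------------------------------------

def build_graymatter_mask(density: Volume4D, threshold: float = 0.2) -> Mask3D:
    """Threshold a tissue-density map (values in [0, 1]) strictly above ``threshold``."""
    if not 0 < threshold < 1:
        raise ValidationError(f"threshold must be in (0, 1), got {threshold}")
    d = density.data[..., 0]
    if d.min() < -1e-9 or d.max() > 1 + 1e-9:
        raise ValidationError(
            f"density values must lie in [0, 1]; observed range [{d.min():g}, {d.max():g}]"
        )
    return Mask3D(data=(d > threshold), affine=density.affine)


def build_functional_mask(vol: Volume4D, percentile: float = 20.0) -> Mask3D:
    """Mask of voxels whose temporal minimum exceeds the given percentile.

    The per-voxel minimum over time is low where the scan has signal dropout,
    so thresholding the map of temporal minima keeps well-covered voxels.
    The percentile is the linear-interpolation estimator over all in-grid
    voxels; comparison is strict, so ties at the threshold are excluded.
    """
    if not 0 < percentile < 100:
        raise ValidationError(f"percentile must be in (0, 100), got {percentile}")
    minima = vol.data.min(axis=3)
    thr = np.percentile(minima, percentile)
    return Mask3D(data=(minima > thr), affine=vol.affine)


def _check_same_grid(masks: Sequence[Mask3D]) -> None:
    ref = masks[0]
    for m in masks[1:]:
        if m.shape != ref.shape:
            raise ShapeError(f"mask grids differ: {m.shape} vs {ref.shape}")
        if not _check_affines(m.affine, ref.affine):
            raise ShapeError("mask affines differ beyond tolerance")


def combine_group_masks(masks: Sequence[Mask3D], fraction: float = 0.75) -> Mask3D:
    """Voxels present in at least ``fraction`` of the subject masks (inclusive)."""
    if len(masks) < 1:
        raise ValidationError("need at least one mask")
    if not 0 < fraction <= 1:
        raise ValidationError(f"fraction must be in (0, 1], got {fraction}")
    _check_same_grid(masks)
    mean = np.mean([m.data for m in masks], axis=0)
    return Mask3D(data=(mean >= fraction - 1e-12), affine=masks[0].affine)


def intersect_masks(masks: Sequence[Mask3D], exclusions: Sequence[Mask3D] = ()) -> Mask3D:
    """Voxelwise AND over ``masks``, then AND NOT over ``exclusions``."""
    if len(masks) < 1:
        raise ValidationError("need at least one mask")
    _check_same_grid(list(masks) + list(exclusions))
    out = np.ones(masks[0].shape, dtype=bool)
    for m in masks:
        out &= m.data.astype(bool)
    for e in exclusions:
        out &= ~e.data.astype(bool)
    return Mask3D(data=out, affine=masks[0].affine)


# ---------------------------------------------------------------------------
# Grid <-> matrix conversion
# ---------------------------------------------------------------------------

def _flat_order_index(mask: Mask3D) -> np.ndarray:
    """Flat (Fortran-order) indices of in-mask voxels, x fastest."""
    return np.flatnonzero(mask.data.ravel(order="F"))


def mask_coordinates(mask: Mask3D) -> np.ndarray:
    """``count x 3`` array of (x, y, z) coordinates in row-traversal order."""
    flat = _flat_order_index(mask)
    coords = np.unravel_index(flat, mask.shape, order="F")
    return np.stack(coords, axis=1)


def extract_timeseries(vol: Volume4D, mask: Mask3D) -> TimeSeriesMatrix:
    """Extract the ``N x T`` matrix of in-mask voxel time series."""
    if vol.shape3d != mask.shape:
        raise ShapeError(f"volume grid {vol.shape3d} does not match mask grid {mask.shape}")
    if not _check_affines(vol.affine, mask.affine):
        raise ShapeError("volume and mask affines differ beyond tolerance")
    if mask.count < 1:
        raise ValidationError("mask is empty")
    flat = _flat_order_index(mask)
    n_vox = int(np.prod(vol.shape3d))
    values = vol.data.reshape(n_vox, vol.n_volumes, order="F")[flat]
    return TimeSeriesMatrix(values=values, voxel_index=mask_coordinates(mask), tr=vol.tr)


def insert_map(
    values: np.ndarray,
    mask: Mask3D,
    fill: float = 0.0,
    tr: float = 1.0,
) -> Volume4D:
    """Place a length-N vector (or ``N x M`` matrix) back onto the mask grid.

    Columns become frames of the output volume; out-of-mask voxels get
    ``fill``.  Exact inverse of :func:`extract_timeseries` on in-mask voxels.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1 and mask.count != 1:
        values = values.T
    if values.shape[0] != mask.count:
        raise ShapeError(
            f"value rows ({values.shape[0]}) do not match mask count ({mask.count})"
        )
    flat = _flat_order_index(mask)
    n_vox = int(np.prod(mask.shape))
    grid = np.full((n_vox, values.shape[1]), float(fill))
    grid[flat] = values
    data = grid.reshape(mask.shape + (values.shape[1],), order="F")
    vsize = tuple(float(v) for v in np.linalg.norm(mask.affine[:3, :3], axis=0))
    return Volume4D(data=data, affine=mask.affine, voxel_size=vsize, tr=tr)
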