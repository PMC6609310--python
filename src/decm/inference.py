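"""Between-group inference on dual-regression maps.

The observed pipeline is: voxelwise GLM contrast t-map -> threshold-free
cluster enhancement (TFCE) -> family-wise error (FWE) correction against
the permutation distribution of the image-wide maximum enhanced statistic.
Comparing each voxel with the *maximum* over the image achieves location
independence and therefore FWE control at the stated level.

Nuisance covariates (scan length) are handled under permutation with the
Freedman–Lane scheme: the data are residualized on the nuisance columns,
the residual rows are permuted, the nuisance fit is added back, and the
full model is re-fit.  Plain label permutation is available via
``scheme="labels"``.

Corrected p-values use the ``(1 + b) / (1 + n_perm)`` estimator, so p is
never exactly zero and the test is exact-level for exchangeable nulls.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations as _iter_permutations

import numpy as np
import pandas as pd
from scipy import ndimage

from ._tfce import MaskGraph, tfce_on_graph
from .errors import DegenerateDesignError, ValidationError
from .volumes import Mask3D, mask_coordinates

__all__ = [
    "GroupDesign",
    "TfceParams",
    "PermutationResult",
    "median_split",
    "make_group_design",
    "glm_contrast_tmap",
    "tfce",
    "permutation_fwe",
    "bonferroni_threshold",
    "cluster_report",
]


@dataclass
class GroupDesign:
    """Subjects x P design matrix with a contrast vector.

    Typical layout: a group indicator, a scan-length covariate and an
    intercept, with contrast ``[±1, 0, 0]`` testing the group difference.
    """

    design: np.ndarray
    contrast: np.ndarray
    labels: list[str] = field(default_factory=list)
    column_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.design = np.atleast_2d(np.asarray(self.design, dtype=float))
        self.contrast = np.asarray(self.contrast, dtype=float)
        s, p = self.design.shape
        if self.contrast.shape != (p,):
            raise ValidationError("contrast length must equal design columns")
        if not np.any(self.contrast):
            raise ValidationError("contrast must be nonzero")
        if s < p + 2:
            raise ValidationError(f"need at least P+2 subjects (S={s}, P={p})")
        if np.linalg.matrix_rank(self.design) < p:
            raise DegenerateDesignError("design matrix is rank deficient")
        if not self.column_names:
            self.column_names = [f"x{i}" for i in range(p)]

    @property
    def n_subjects(self) -> int:
        return self.design.shape[0]


@dataclass
class TfceParams:
    """TFCE parameters: defaults E=0.5, H=2, 26-connectivity, dh=max/100."""

    e_exponent: float = 0.5
    h_exponent: float = 2.0
    dh: float | None = None
    connectivity: int = 26
    n_steps: int = 100

    def __post_init__(self) -> None:
        if self.e_exponent < 0 or self.h_exponent < 0:
            raise ValidationError("TFCE exponents must be nonnegative")
        if self.dh is not None and self.dh <= 0:
            raise ValidationError("dh must be positive")


@dataclass
class PermutationResult:
    """Observed statistics, enhanced statistics, FWE p-values and the null sample."""

    tmap: np.ndarray
    tfce_map: np.ndarray
    pcorr: np.ndarray
    null_max: np.ndarray
    n_perm: int
    seed: int


def median_split(ages: np.ndarray | list[float]) -> np.ndarray:
    """Label subjects 'young' (below the median) or 'old' (at or above).

    Ties at the median go to the older group, so the split is deterministic.
    """
    ages = np.asarray(ages, dtype=float)
    if ages.size < 2:
        raise ValidationError("need at least 2 subjects for a median split")
    if np.ptp(ages) == 0:
        raise ValidationError("all ages identical; median split is degenerate")
    med = np.median(ages)
    return np.where(ages < med, "young", "old")


def make_group_design(
    groups: np.ndarray | list[str],
    covariates: np.ndarray | None = None,
    labels: list[str] | None = None,
    direction: int = 1,
) -> GroupDesign:
    """Two-group design: indicator (+1/-1 coded), optional covariates, intercept.

    The contrast tests group A minus group B (``direction=+1``) or the
    reverse.  Covariates are demeaned so the intercept stays interpretable.
    """
    groups = np.asarray(groups)
    names = sorted(set(groups.tolist()))
    if len(names) != 2:
        raise ValidationError(f"expected exactly 2 groups, got {names}")
    indicator = np.where(groups == names[0], 1.0, -1.0)
    cols = [indicator]
    col_names = [f"{names[0]}_vs_{names[1]}"]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != groups.size:
            cov = cov.T
        cov = cov - cov.mean(axis=0)
        for i in range(cov.shape[1]):
            cols.append(cov[:, i])
            col_names.append(f"covar_{i}")
    cols.append(np.ones(groups.size))
    col_names.append("intercept")
    contrast = np.zeros(len(cols))
    contrast[0] = float(direction)
    return GroupDesign(
        design=np.column_stack(cols),
        contrast=contrast,
        labels=list(labels) if labels else [],
        column_names=col_names,
    )


def glm_contrast_tmap(maps: np.ndarray, d: GroupDesign) -> np.ndarray:
    """Voxelwise OLS contrast t-statistics, ``t = c'b / se(c'b)``.

    Voxels with zero residual variance get t = 0 (counted in a warning).
    """
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    if maps.shape[0] != d.n_subjects:
        raise ValidationError("map rows must equal number of subjects")
    x = d.design
    s, p = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    pinv = xtx_inv @ x.T
    beta = pinv @ maps
    resid = maps - x @ beta
    dof = s - p
    sigma2 = (resid**2).sum(axis=0) / dof
    varc = float(d.contrast @ xtx_inv @ d.contrast)
    effect = d.contrast @ beta
    scale = np.maximum(np.abs(maps).max(initial=0.0), 1.0)
    zero_var = sigma2 <= (1e-14 * scale) ** 2
    n_zero = int(zero_var.sum())
    if n_zero:
        warnings.warn(
            f"{n_zero} voxel(s) with zero residual variance; t set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(varc * sigma2)
    t[zero_var] = 0.0
    return t


def tfce(
    stat: np.ndarray,
    mask: Mask3D,
    params: TfceParams | None = None,
    graph: MaskGraph | None = None,
) -> np.ndarray:
    """TFCE-enhance a statistic vector defined on the mask voxels."""
    params = params or TfceParams()
    if graph is None:
        graph = MaskGraph(mask, connectivity=params.connectivity)
    return tfce_on_graph(
        stat, graph, params.e_exponent, params.h_exponent, params.dh, params.n_steps
    )


def _partition_design(d: GroupDesign) -> tuple[np.ndarray, np.ndarray | None]:
    """Split design columns into effect-of-interest and nuisance by the contrast."""
    interest = d.contrast != 0
    z = d.design[:, ~interest]
    return d.design[:, interest], (z if z.shape[1] else None)


def permutation_fwe(
    maps: np.ndarray,
    d: GroupDesign,
    mask: Mask3D,
    params: TfceParams | None = None,
    n_perm: int = 10000,
    seed: int = 0,
    scheme: str = "freedman-lane",
    graph: MaskGraph | None = None,
) -> PermutationResult:
    """Max-statistic permutation FWE correction of the TFCE-enhanced contrast.

    For each permutation the pipeline (GLM t-map -> TFCE) is recomputed and
    the image-wide maximum enhanced statistic stored; the corrected p-value
    of a voxel is ``(1 + #{null_max >= observed}) / (1 + n_perm)``.
    Deterministic given ``seed``.  If fewer distinct permutations exist than
    requested, they are enumerated exhaustively (with a notice).
    """
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    params = params or TfceParams()
    if n_perm < 100:
        raise ValidationError("need at least 100 permutations")
    if scheme not in ("freedman-lane", "labels"):
        raise ValidationError(f"unknown permutation scheme {scheme!r}")
    s = d.n_subjects
    if maps.shape[0] != s:
        raise ValidationError("map rows must equal number of subjects")
    if graph is None:
        graph = MaskGraph(mask, connectivity=params.connectivity)
    if graph.n_voxels != maps.shape[1]:
        raise ValidationError("map columns must equal mask voxel count")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t_obs = glm_contrast_tmap(maps, d)
    # fix dh from the observed map so null and observed are on one scale
    run_params = params
    if params.dh is None:
        vmax = float(np.abs(t_obs).max(initial=0.0))
        dh = vmax / params.n_steps if vmax > 0 else 1.0
        run_params = TfceParams(
            e_exponent=params.e_exponent,
            h_exponent=params.h_exponent,
            dh=dh,
            connectivity=params.connectivity,
            n_steps=0,
        )
    tfce_obs = tfce(t_obs, mask, run_params, graph=graph)

    if scheme == "freedman-lane":
        _, z = _partition_design(d)
        if z is not None:
            hz = z @ np.linalg.pinv(z)
            fit = hz @ maps
            resid = maps - fit
        else:
            fit = np.zeros_like(maps)
            resid = maps
    else:
        fit = np.zeros_like(maps)
        resid = maps

    rng = np.random.default_rng(seed)
    n_distinct = math.factorial(s) if s <= 12 else None
    if n_distinct is not None and n_distinct <= n_perm:
        warnings.warn(
            f"only {n_distinct} distinct permutations exist; enumerating exhaustively",
            RuntimeWarning,
            stacklevel=2,
        )
        perms = [np.asarray(p) for p in _iter_permutations(range(s))]
    else:
        perms = [rng.permutation(s) for _ in range(n_perm)]
    n_used = len(perms)

    null_max = np.empty(n_used)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for b, perm in enumerate(perms):
            yb = fit + resid[perm]
            tb = glm_contrast_tmap(yb, d)
            null_max[b] = tfce(tb, mask, run_params, graph=graph).max(initial=0.0)

    null_sorted = np.sort(null_max)
    exceed = n_used - np.searchsorted(null_sorted, tfce_obs, side="left")
    pcorr = (1.0 + exceed) / (1.0 + n_used)
    return PermutationResult(
        tmap=t_obs,
        tfce_map=tfce_obs,
        pcorr=pcorr,
        null_max=null_max,
        n_perm=n_used,
        seed=seed,
    )


def bonferroni_threshold(alpha: float = 0.05, k_networks: int = 1) -> float:
    """Across-network Bonferroni adjustment of the significance threshold."""
    if k_networks < 1:
        raise ValidationError("k_networks must be >= 1")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    return alpha / k_networks


def cluster_report(
    pcorr: np.ndarray,
    stat: np.ndarray,
    mask: Mask3D,
    alpha: float = 0.05,
    min_size: int = 10,
    connectivity: int = 26,
) -> pd.DataFrame:
    """Table of suprathreshold clusters with more than ``min_size`` voxels.

    Components of ``{pcorr < alpha}`` are labelled under the given
    connectivity; each row reports extent, peak |statistic|, peak voxel
    coordinate and the smallest corrected p inside the cluster.
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    if min_size < 1:
        raise ValidationError("min_size must be >= 1")
    coords = mask_coordinates(mask)
    sig = np.zeros(mask.shape, dtype=bool)
    sel = pcorr < alpha
    sig[coords[sel, 0], coords[sel, 1], coords[sel, 2]] = True
    if connectivity == 26:
        structure = np.ones((3, 3, 3), dtype=bool)
    elif connectivity == 18:
        structure = ndimage.generate_binary_structure(3, 2)
    else:
        structure = ndimage.generate_binary_structure(3, 1)
    labels, n_comp = ndimage.label(sig, structure=structure)
    stat_grid = np.zeros(mask.shape)
    p_grid = np.ones(mask.shape)
    stat_grid[coords[:, 0], coords[:, 1], coords[:, 2]] = stat
    p_grid[coords[:, 0], coords[:, 1], coords[:, 2]] = pcorr
    rows = []
    for comp in range(1, n_comp + 1):
        member = labels == comp
        size = int(member.sum())
        if size <= min_size:
            continue
        vals = np.abs(stat_grid[member])
        peak_local = int(np.argmax(vals))
        xyz = np.argwhere(member)[peak_local]
        rows.append(
            {
                "size": size,
                "peak_stat": float(stat_grid[tuple(xyz)]),
                "peak_x": int(xyz[0]),
                "peak_y": int(xyz[1]),
                "peak_z": int(xyz[2]),
                "min_pcorr": float(p_grid[member].min()),
            }
        )
    rows.sort(key=lambda r: -r["size"])
    return pd.DataFrame(
        rows, columns=["size", "peak_stat", "peak_x", "peak_y", "peak_z", "min_pcorr"]
    )
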