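"""End-to-end cohort analysis in memory.

Glue that runs the full dECM study on a :class:`~decm.synthetic.Cohort`
(or any equivalently structured inputs): confound regression, sliding-window
centrality, dual regression, and per-network permutation inference.  The
file-based pipeline and the command line are thin wrappers around these
functions; tests and simulations call them directly to avoid I/O.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .confounds import ConfoundTable, regress_confounds
from .dualregression import (
    SubjectSpatialMaps,
    SubjectTimecourses,
    TemplateSet,
    dual_regression,
    make_network_mask,
)
from .errors import ValidationError
from .inference import (
    MaskGraph,
    PermutationResult,
    TfceParams,
    make_group_design,
    permutation_fwe,
)
from .sliding import CentralitySeries, sliding_window_ecm
from .synthetic import Cohort
from .volumes import Mask3D, extract_timeseries

__all__ = [
    "SubjectResult",
    "run_subject",
    "run_cohort_dualreg",
    "network_mask_selector",
    "run_network_inference",
]


@dataclass
class SubjectResult:
    """Per-subject products of the dECM + dual-regression stages."""

    centrality: CentralitySeries
    timecourses: SubjectTimecourses  # stage-1, unnormalized
    maps: SubjectSpatialMaps  # stage-2 coefficients
    window_length: int


def run_subject(
    vol,
    mask: Mask3D,
    templates: TemplateSet,
    n_maps: int,
    confound: np.ndarray | None = None,
    target_mean: float = 4500.0,
    normalize_courses: bool = True,
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> SubjectResult:
    """Masking -> (optional) confound regression -> dECM -> dual regression."""
    ts = extract_timeseries(vol, mask)
    if confound is not None:
        ts = regress_confounds(ts, ConfoundTable(values=confound))
    cs = sliding_window_ecm(
        ts, n_maps=n_maps, tol=tol, max_iter=max_iter, target_mean=target_mean
    )
    s, d = dual_regression(cs, templates, normalize=normalize_courses)
    return SubjectResult(
        centrality=cs, timecourses=s, maps=d, window_length=cs.window_length
    )


def run_cohort_dualreg(
    cohort: Cohort,
    n_maps: int,
    target_mean: float = 4500.0,
    use_confounds: bool = True,
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> list[SubjectResult]:
    """Run every subject of a cohort through the subject-level stages."""
    results = []
    for vol, conf in zip(cohort.subjects, cohort.confounds):
        results.append(
            run_subject(
                vol,
                cohort.brain_mask,
                cohort.templates,
                n_maps=n_maps,
                confound=conf if use_confounds else None,
                target_mean=target_mean,
                tol=tol,
                max_iter=max_iter,
            )
        )
    return results


def network_mask_selector(
    templates: TemplateSet, k: int, mask: Mask3D
) -> tuple[Mask3D, np.ndarray]:
    """Network mask plus the boolean selector of its voxels within the analysis mask."""
    net_mask = make_network_mask(templates, k, mask)
    supra = templates.maps[:, k] > templates.zthreshold
    if not supra.any():
        raise ValidationError(f"network {templates.names[k]!r} has no suprathreshold voxels")
    return net_mask, supra


def run_network_inference(
    results: list[SubjectResult],
    cohort: Cohort,
    network: int,
    n_perm: int = 10000,
    seed: int = 0,
    params: TfceParams | None = None,
    direction: int = 1,
    contrast_on: str = "group",
    graph: MaskGraph | None = None,
    net_geometry: tuple[Mask3D, np.ndarray] | None = None,
) -> tuple[PermutationResult, Mask3D]:
    """Group inference on one network's stage-2 maps inside its own mask.

    The design carries the two-group contrast (on ``contrast_on`` of the
    cohort design table) plus a scan-length covariate when scan lengths
    vary across subjects.
    """
    if net_geometry is None:
        net_geometry = network_mask_selector(cohort.templates, network, cohort.brain_mask)
    net_mask, sel = net_geometry
    maps = np.stack([r.maps.values[sel, network] for r in results])
    groups = cohort.design[contrast_on].to_numpy()
    scan = cohort.design["scan_length"].to_numpy(float)
    covariates = scan[:, None] if np.ptp(scan) > 0 else None
    design = make_group_design(
        groups,
        covariates=covariates,
        labels=cohort.design["subject"].tolist(),
        direction=direction,
    )
    res = permutation_fwe(
        maps, design, net_mask, params=params, n_perm=n_perm, seed=seed, graph=graph
    )
    return res, net_mask
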