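"""Method-validation experiments: oracle checks and simulation studies.

These are the package's own correctness experiments, runnable on one CPU in
minutes: equivalence of the matrix-free centrality against a dense
eigendecomposition oracle, type-I-error calibration of the permutation test
on null synthetic cohorts, and recovery of a planted coupling-variability
difference by the full pipeline.  The test suite and the acceptance script
both drive these functions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .centrality import ecm_power_iteration, normalize_rows
from .inference import TfceParams, cluster_report
from .study import network_mask_selector, run_cohort_dualreg, run_network_inference
from .synthetic import SynthConfig, generate_cohort

__all__ = [
    "ecm_oracle_max_error",
    "CalibrationResult",
    "type_one_error_calibration",
    "RecoveryResult",
    "planted_effect_recovery",
]

#: Conditions for the null-calibration study: a small two-network cohort of
#: 8 subjects per group, 60 volumes, 30 window positions.
CALIBRATION_CONFIG = SynthConfig(
    grid=(14, 14, 10), t_len=60, n_networks=2, n_per_group=8
).null()
CALIBRATION_N_MAPS = 30


def ecm_oracle_max_error(
    n_instances: int = 100,
    seed: int = 0,
    max_voxels: int = 50,
    max_window: int = 40,
) -> float:
    """Worst-case deviation of matrix-free ECM from the dense R+1 eigenvector.

    Draws random voxel-by-time instances, runs the matrix-free power
    iteration, and compares with the dominant eigenvector of the explicitly
    formed ``R + 1`` (dense eigendecomposition), after sign alignment.
    Returns the maximum absolute elementwise difference over all instances.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(2, max_voxels + 1))
        w = int(rng.integers(3, max_window + 1))
        ns = normalize_rows(rng.standard_normal((n, w)))
        cv = ecm_power_iteration(ns)
        dense = ns.rows @ ns.rows.T + 1.0
        _, vecs = np.linalg.eigh(dense)
        ref = vecs[:, -1]
        ref = ref * np.sign(ref.sum())
        worst = max(worst, float(np.abs(cv.values - ref).max()))
    return worst


@dataclass
class CalibrationResult:
    rejection_fraction: float
    n_cohorts: int
    min_pcorrs: np.ndarray


def type_one_error_calibration(
    n_cohorts: int = 200,
    n_perm: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
    n_maps: int = CALIBRATION_N_MAPS,
) -> CalibrationResult:
    """Family-wise rejection rate of the full pipeline on null cohorts.

    Each cohort is generated with *no* group difference, pushed through
    confound-free dECM + dual regression, and tested with TFCE +
    max-statistic permutation FWE inside the first network's mask (one
    contrast direction = one test family).  For an exact-level procedure
    the fraction of cohorts with min corrected p < ``alpha`` should sit
    near ``alpha``.
    """
    rng = np.random.SeedSequence(seed)
    cohort_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in rng.spawn(2 * n_cohorts)]
    min_ps = np.empty(n_cohorts)
    for i in range(n_cohorts):
        cfg = replace(CALIBRATION_CONFIG, seed=cohort_seeds[2 * i])
        cohort = generate_cohort(cfg)
        results = run_cohort_dualreg(cohort, n_maps=n_maps, use_confounds=False)
        res, _ = run_network_inference(
            results,
            cohort,
            network=0,
            n_perm=n_perm,
            seed=cohort_seeds[2 * i + 1],
            direction=1,
        )
        min_ps[i] = res.pcorr.min()
    return CalibrationResult(
        rejection_fraction=float((min_ps < alpha).mean()),
        n_cohorts=n_cohorts,
        min_pcorrs=min_ps,
    )


@dataclass
class RecoveryResult:
    detection_rate: float
    planted_detected: int
    null_network_flagged: int
    n_replicates: int
    planted_min_pcorrs: np.ndarray


def planted_effect_recovery(
    n_replicates: int = 20,
    n_perm: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
    n_maps: int = 60,
    config: SynthConfig | None = None,
) -> RecoveryResult:
    """Detection of the planted coupling-variability difference.

    For each replicate a default cohort (two-fold coupling-variability
    ratio in the effect network) is analysed end to end.  The planted
    network counts as detected when any voxel inside its mask reaches
    FWE-corrected p < ``alpha`` for the matched contrast direction (more
    variable group > control).  A null control network counts as falsely
    flagged when either contrast direction yields an FWE-significant
    cluster of more than 10 voxels — the study's cluster reporting rule.
    """
    base = config or SynthConfig()
    rng = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in rng.spawn(2 * n_replicates)]
    null_network = 1 if base.effect_network != 1 else 0
    detected = 0
    flagged = 0
    min_ps = np.empty(n_replicates)
    params = TfceParams()
    for i in range(n_replicates):
        cohort = generate_cohort(replace(base, seed=rep_seeds[2 * i]))
        results = run_cohort_dualreg(cohort, n_maps=n_maps, use_confounds=False)
        res, _ = run_network_inference(
            results,
            cohort,
            network=base.effect_network,
            n_perm=n_perm,
            seed=rep_seeds[2 * i + 1],
            params=params,
            direction=-1,  # group B (more variable) > group A
        )
        min_ps[i] = res.pcorr.min()
        detected += min_ps[i] < alpha
        geometry = network_mask_selector(cohort.templates, null_network, cohort.brain_mask)
        for direction in (1, -1):
            resn, net_mask = run_network_inference(
                results,
                cohort,
                network=null_network,
                n_perm=n_perm,
                seed=rep_seeds[2 * i + 1] + direction,
                params=params,
                direction=direction,
                net_geometry=geometry,
            )
            table = cluster_report(resn.pcorr, resn.tmap, net_mask, alpha=alpha, min_size=10)
            if len(table):
                flagged += 1
                break
    return RecoveryResult(
        detection_rate=detected / n_replicates,
        planted_detected=int(detected),
        null_network_flagged=int(flagged),
        n_replicates=n_replicates,
        planted_min_pcorrs=min_ps,
    )
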