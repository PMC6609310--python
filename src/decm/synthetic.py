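"""Synthetic multi-subject resting-state fMRI with planted network dynamics.

The generator emulates the statistical structure the dECM analysis assumes:

* ``K`` spatially smooth "networks" — Gaussian blobs on a small ellipsoidal
  brain mask, Z-scored over the mask to play the role of RSN templates;
* a latent time course per network, shared by the network's voxels;
* a *time-varying within-network coupling* ``c_k(t)``: each voxel mixes the
  shared course (weight ``c``) with private noise (weight ``sqrt(1-c^2)``),
  so the instantaneous within-network correlation is ``~c(t)^2``.  The
  coupling drifts slowly — a random-sign monotone trend over the scan plus
  a small smoothed random-walk wobble, standardized so each subject's
  realized within-scan coupling variability *equals* the group's
  ``coupling_sd``.  That standard deviation is the group-difference knob:
  the group with larger coupling variability shows larger temporal
  variation in within-network eigenvector centrality;
* additive white measurement noise, and optional motion-like confound
  columns.

The monotone drift shape matters: sliding windows of length ``W ~ T/2``
low-pass the coupling trajectory so heavily that a free random walk would
leave each subject's *realized* windowed drift amplitude with only ~2
degrees of freedom — a coefficient of variation near 0.5 that would swamp
a factor-two group difference at 10 subjects per group.  A monotone drift
survives windowing with a deterministic amplitude, so the planted
variability ratio is actually present in every subject.

Randomness is organized as common random numbers: templates, latent
courses, walk *shapes* and noise are drawn from streams that do not depend
on the group parameters, and the group's ``coupling_sd`` only rescales the
walk.  Changing the effect size therefore changes the coupling
trajectories and nothing else, and a fixed master seed reproduces the
cohort byte for byte.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .dualregression import TemplateSet
from .errors import ValidationError
from .volumes import Mask3D, Volume4D, insert_map, mask_coordinates

__all__ = ["SynthConfig", "Cohort", "generate_templates", "generate_subject", "generate_cohort"]


@dataclass
class SynthConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe a small two-group study: a 20 x 20 x 12 grid (3 mm
    voxels) so the full pipeline runs in minutes on one CPU, 120 volumes at
    TR 2.5 s, 4 networks, 10 subjects per group, and a two-fold difference
    in coupling variability planted in ``effect_network`` (group "B" is the
    more variable one).  ``coupling_sd`` of (0.18, 0.36) around a mean
    coupling of 0.55 spans within-network window correlations of roughly
    0.1-0.6, the range sliding-window fMRI studies report.
    ``drift_wobble`` is the fraction of the coupling drift carried by the
    stochastic (smoothed random-walk) component rather than the monotone
    trend.
    """

    grid: tuple[int, int, int] = (20, 20, 12)
    t_len: int = 120
    n_networks: int = 4
    blob_centers: tuple[tuple[int, int, int], ...] | None = None
    blob_width: float = 2.5
    coupling_mean: float = 0.55
    coupling_sd: tuple[float, float] = (0.18, 0.36)
    drift_wobble: float = 0.15
    noise_sd: float = 0.3
    n_per_group: int = 10
    effect_network: int = 0
    seed: int = 0
    tr: float = 2.5
    scan_lengths: tuple[int, ...] | None = None
    n_motion_confounds: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.coupling_mean < 1:
            raise ValidationError("coupling_mean must be in (0, 1)")
        if self.n_networks < 1:
            raise ValidationError("need at least one network")
        if self.blob_centers is not None and len(self.blob_centers) != self.n_networks:
            raise ValidationError("one blob center per network required")

    def null(self) -> "SynthConfig":
        """The matched no-effect configuration (equal coupling variability)."""
        return replace(self, coupling_sd=(self.coupling_sd[0], self.coupling_sd[0]))


@dataclass
class Cohort:
    """A generated two-group cohort plus everything the pipeline needs."""

    subjects: list[Volume4D]
    truths: list[dict]
    confounds: list[np.ndarray | None]
    templates: TemplateSet
    brain_mask: Mask3D
    design: pd.DataFrame
    weights: np.ndarray = field(repr=False, default=None)


_GROUPS = ("A", "B")
_AFFINE = np.diag([3.0, 3.0, 3.0, 1.0])


def _default_centers(cfg: SynthConfig) -> np.ndarray:
    x, y, z = cfg.grid
    angles = 2 * np.pi * (np.arange(cfg.n_networks) + 0.5) / cfg.n_networks
    cx = x / 2 + (x / 3.6) * np.cos(angles)
    cy = y / 2 + (y / 3.6) * np.sin(angles)
    cz = np.full(cfg.n_networks, z / 2)
    return np.stack([cx, cy, cz], axis=1)


def brain_mask(cfg: SynthConfig) -> Mask3D:
    """Ellipsoidal 'brain' inscribed in the grid."""
    x, y, z = cfg.grid
    xi, yi, zi = np.meshgrid(np.arange(x), np.arange(y), np.arange(z), indexing="ij")
    r = (
        ((xi - (x - 1) / 2) / (0.48 * x)) ** 2
        + ((yi - (y - 1) / 2) / (0.48 * y)) ** 2
        + ((zi - (z - 1) / 2) / (0.48 * z)) ** 2
    )
    return Mask3D(data=(r <= 1.0), affine=_AFFINE)


def _blob_weights(cfg: SynthConfig, mask: Mask3D) -> np.ndarray:
    """``N x K`` Gaussian spatial profiles (max ~1 at each blob center)."""
    centers = (
        np.asarray(cfg.blob_centers, dtype=float)
        if cfg.blob_centers is not None
        else _default_centers(cfg)
    )
    if len(np.unique(centers.round(6), axis=0)) < len(centers):
        warnings.warn("identical blob centers: networks overlap completely", RuntimeWarning)
    coords = mask_coordinates(mask).astype(float)
    d2 = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-d2 / (2.0 * cfg.blob_width**2))


def generate_templates(cfg: SynthConfig) -> tuple[TemplateSet, Mask3D]:
    """K blob templates, Z-scored over the brain mask; deterministic given cfg."""
    mask = brain_mask(cfg)
    w = _blob_weights(cfg, mask)
    z = (w - w.mean(axis=0)) / w.std(axis=0)
    names = [f"network_{i}" for i in range(cfg.n_networks)]
    return TemplateSet(maps=z, names=names, zthreshold=3.0), mask


def _standardize(x: np.ndarray, axis: int = -1) -> np.ndarray:
    x = x - x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, keepdims=True)
    return x / np.where(sd == 0, 1.0, sd)


def generate_subject(
    cfg: SynthConfig,
    group: str,
    subject_seed: int | np.random.SeedSequence,
    t_len: int | None = None,
) -> tuple[Volume4D, dict]:
    """One subject's 4-D volume plus a truth record.

    The truth record stores the latent network courses, the coupling
    trajectories and the group, for end-to-end checks of planted effects.
    """
    if group not in _GROUPS:
        raise ValidationError(f"group must be one of {_GROUPS}")
    t = int(t_len or cfg.t_len)
    k = cfg.n_networks
    mask = brain_mask(cfg)
    w = _blob_weights(cfg, mask)
    n = w.shape[0]
    ss = (
        subject_seed
        if isinstance(subject_seed, np.random.SeedSequence)
        else np.random.SeedSequence(subject_seed)
    )
    latent_rng, walk_rng, noise_rng, motion_rng = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )

    # shared network courses: white, unit variance (stable window variance)
    latent = _standardize(latent_rng.standard_normal((k, t)))

    # coupling trajectories: unit-sd drift shape (monotone trend + wobble)
    # scaled by the group's coupling_sd
    sign = walk_rng.choice([-1.0, 1.0], size=k)
    ramp = np.sqrt(3.0) * (2.0 * np.arange(t) / (t - 1) - 1.0)  # unit-sd line
    wobble = _standardize(
        gaussian_filter1d(np.cumsum(walk_rng.standard_normal((k, t)), axis=1), sigma=t / 8, axis=1)
    )
    shape = (
        np.sqrt(1.0 - cfg.drift_wobble**2) * sign[:, None] * ramp[None, :]
        + cfg.drift_wobble * wobble
    )
    sd_group = cfg.coupling_sd[_GROUPS.index(group)]
    sds = np.where(np.arange(k) == cfg.effect_network, sd_group, cfg.coupling_sd[0])
    coupling = np.clip(cfg.coupling_mean + sds[:, None] * shape, 0.05, 0.98)

    private = noise_rng.standard_normal((k, n, t))
    measurement = noise_rng.standard_normal((n, t))

    shared = coupling * latent  # (K, T)
    mix = np.sqrt(1.0 - coupling**2)  # (K, T)
    data = np.einsum("nk,kt->nt", w, shared)
    for ki in range(k):
        data += w[:, ki : ki + 1] * (mix[ki] * private[ki])
    data += cfg.noise_sd * measurement

    confound = None
    if cfg.n_motion_confounds > 0:
        confound = _standardize(
            np.cumsum(motion_rng.standard_normal((cfg.n_motion_confounds, t)), axis=1)
        ).T
        loadings = 0.3 * motion_rng.standard_normal((n, cfg.n_motion_confounds))
        data += loadings @ confound.T

    vol = insert_map(data, mask, fill=0.0, tr=cfg.tr)
    truth = {
        "group": group,
        "latent": latent,
        "coupling": coupling,
        "coupling_sd": sds.copy(),
        "confound": confound,
    }
    return vol, truth


def generate_cohort(cfg: SynthConfig) -> Cohort:
    """Balanced two-group cohort with per-subject seeds from the master seed."""
    if cfg.n_per_group < 2:
        raise ValidationError("need at least 2 subjects per group")
    templates, mask = generate_templates(cfg)
    weights = _blob_weights(cfg, mask)
    n_subjects = 2 * cfg.n_per_group
    master = np.random.SeedSequence(cfg.seed)
    subject_seeds = master.spawn(n_subjects)
    age_rng = np.random.default_rng(master.spawn(1)[0])
    # study-like demographics: young adult cohort, mean ~24.7 y, sd ~2.4 y
    ages = 24.7 + 2.4 * age_rng.standard_normal(n_subjects)

    subjects: list[Volume4D] = []
    truths: list[dict] = []
    confounds: list[np.ndarray | None] = []
    rows = []
    for i in range(n_subjects):
        group = _GROUPS[i % 2]
        if cfg.scan_lengths is not None:
            t_len = int(cfg.scan_lengths[i % len(cfg.scan_lengths)])
        else:
            t_len = cfg.t_len
        vol, truth = generate_subject(cfg, group, subject_seeds[i], t_len=t_len)
        subjects.append(vol)
        truths.append(truth)
        confounds.append(truth["confound"])
        rows.append(
            {
                "subject": f"sub-{i:03d}",
                "group": group,
                "age": round(float(ages[i]), 1),
                "scan_length": t_len,
            }
        )
    design = pd.DataFrame(rows)
    return Cohort(
        subjects=subjects,
        truths=truths,
        confounds=confounds,
        templates=templates,
        brain_mask=mask,
        design=design,
        weights=weights,
    )
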