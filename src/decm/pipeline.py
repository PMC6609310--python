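"""Config-driven end-to-end pipeline with file outputs and a manifest.

Stages (masks -> confound regression -> dECM -> dual regression ->
permutation statistics -> summaries) communicate through NIfTI/TSV files in
the output directory, so any stage can be re-run or validated in isolation
with the corresponding CLI subcommand.  A ``manifest.json`` records the
configuration, the package version, and a SHA-256 digest of every output
file; identical config + seed reproduce identical digests.

Config is a YAML/JSON mapping.  Either a ``synthetic`` section (passed to
:class:`~decm.synthetic.SynthConfig`) or explicit input files::

    seed: 0
    n_maps: 60
    target_mean: 4500.0
    n_perm: 500
    alpha: 0.05
    min_cluster_size: 10
    contrast: group            # column of the design table to contrast
    exclude_networks: []       # template names to leave out of testing
    synthetic: {n_per_group: 10, t_len: 120}
    # or:
    subjects:                  # list of {id, func, motion (optional)}
    mask: analysis_mask.nii
    templates: templates.nii
    template_names: names.txt
    design: design.tsv         # subject, group, age, scan_length
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .confounds import load_confounds
from .dualregression import load_template_names, templates_from_volume
from .errors import ValidationError
from .inference import TfceParams, cluster_report
from .study import network_mask_selector, run_network_inference, run_subject
from .summaries import group_mean_ecm, network_curves
from .synthetic import Cohort, SynthConfig, generate_cohort
from .volumes import (
    Mask3D,
    insert_map,
    read_mask,
    read_volume4d,
    write_mask,
    write_volume4d,
)

__all__ = ["load_config", "run_pipeline"]

_DEFAULTS = {
    "seed": 0,
    "n_maps": 60,
    "target_mean": 4500.0,
    "n_perm": 500,
    "alpha": 0.05,
    "min_cluster_size": 10,
    "contrast": "group",
    "exclude_networks": [],
    "zthreshold": 3.0,
    "write_subject_volumes": False,
}


def load_config(source: str | Path | dict) -> dict:
    """Load and validate a pipeline configuration."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(source)
    if not isinstance(cfg, dict):
        raise ValidationError("config must be a mapping")
    out = dict(_DEFAULTS)
    out.update(cfg)
    if "synthetic" not in out:
        for key in ("subjects", "mask", "templates", "design"):
            if key not in out:
                raise ValidationError(f"config missing required key {key!r}")
    if out["n_maps"] < 1:
        raise ValidationError("config key 'n_maps' must be >= 1")
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def _load_real_cohort(cfg: dict) -> Cohort:
    mask = read_mask(cfg["mask"])
    tvol = read_volume4d(cfg["templates"])
    names = load_template_names(cfg["template_names"]) if cfg.get("template_names") else None
    templates = templates_from_volume(tvol, mask, names=names, zthreshold=cfg["zthreshold"])
    design = pd.read_csv(cfg["design"], sep="\t")
    subjects, confounds = [], []
    for sub in cfg["subjects"]:
        vol = read_volume4d(sub["func"])
        subjects.append(vol)
        confounds.append(load_confounds(sub["motion"]).values if sub.get("motion") else None)
        if sub["id"] not in set(design["subject"]):
            raise ValidationError(f"subject {sub['id']!r} missing from design table")
    return Cohort(
        subjects=subjects,
        truths=[{} for _ in subjects],
        confounds=confounds,
        templates=templates,
        brain_mask=mask,
        design=design,
        weights=None,
    )


def run_pipeline(config: str | Path | dict, outdir: str | Path) -> Path:
    """Run the full study replica and return the output directory."""
    cfg = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    # ------------------------------------------------------------------ inputs
    if "synthetic" in cfg:
        synth = SynthConfig(**{**cfg["synthetic"], "seed": cfg["seed"]})
        cohort = generate_cohort(synth)
    else:
        cohort = _load_real_cohort(cfg)
    mask = cohort.brain_mask
    outputs.append(write_mask(mask, outdir / "analysis_mask.nii"))
    outputs.append(
        write_volume4d(insert_map(cohort.templates.maps, mask), outdir / "templates.nii")
    )
    outputs.append(_write_tsv(cohort.design, outdir / "design.tsv"))

    # ------------------------------------------- subject level: dECM + dualreg
    n_maps = int(cfg["n_maps"])
    for vol in cohort.subjects:
        if n_maps > vol.n_volumes - 2:
            sub_id = cohort.design["subject"][cohort.subjects.index(vol)]
            raise ValidationError(
                f"subject {sub_id!r}: {n_maps} maps need at least {n_maps + 2} "
                f"volumes, scan has {vol.n_volumes}"
            )
    results = []
    window_lengths = []
    for i, (vol, conf) in enumerate(zip(cohort.subjects, cohort.confounds)):
        sub_id = cohort.design["subject"][i]
        res = run_subject(
            vol,
            mask,
            cohort.templates,
            n_maps=n_maps,
            confound=conf,
            target_mean=float(cfg["target_mean"]),
        )
        results.append(res)
        window_lengths.append(res.window_length)
        if cfg["write_subject_volumes"]:
            outputs.append(
                write_volume4d(
                    insert_map(res.centrality.values, mask, tr=vol.tr),
                    outdir / f"{sub_id}_ecm.nii",
                )
            )
            outputs.append(
                write_volume4d(
                    insert_map(res.maps.values, mask), outdir / f"{sub_id}_dr_maps.nii"
                )
            )
        tc = pd.DataFrame(res.timecourses.values.T, columns=cohort.templates.names)
        outputs.append(_write_tsv(tc, outdir / f"{sub_id}_timecourses.tsv"))

    # ------------------------------------------------------- group statistics
    tested = [
        k
        for k, name in enumerate(cohort.templates.names)
        if name not in set(cfg["exclude_networks"])
    ]
    params = TfceParams()
    cluster_tables = []
    stats_summary = []
    for k in tested:
        name = cohort.templates.names[k]
        geometry = network_mask_selector(cohort.templates, k, mask)
        for direction, tag in ((1, "pos"), (-1, "neg")):
            res, net_mask = run_network_inference(
                results,
                cohort,
                network=k,
                n_perm=int(cfg["n_perm"]),
                seed=int(cfg["seed"]) + 1000 + k,
                params=params,
                direction=direction,
                contrast_on=cfg["contrast"],
                net_geometry=geometry,
            )
            stats_vol = insert_map(
                np.column_stack([res.tmap, res.tfce_map, 1.0 - res.pcorr]), net_mask
            )
            outputs.append(
                write_volume4d(stats_vol, outdir / f"stats_{name}_{tag}.nii")
            )
            table = cluster_report(
                res.pcorr,
                res.tmap,
                net_mask,
                alpha=float(cfg["alpha"]),
                min_size=int(cfg["min_cluster_size"]),
            )
            table.insert(0, "direction", tag)
            table.insert(0, "network", name)
            cluster_tables.append(table)
            stats_summary.append(
                {
                    "network": name,
                    "direction": tag,
                    "min_pcorr": float(res.pcorr.min()),
                    "max_tfce": float(res.tfce_map.max()),
                    "n_perm": res.n_perm,
                }
            )
    outputs.append(
        _write_tsv(pd.concat(cluster_tables, ignore_index=True), outdir / "clusters.tsv")
    )
    outputs.append(_write_tsv(pd.DataFrame(stats_summary), outdir / "stats_summary.tsv"))

    # ------------------------------------------------------------- summaries
    groups = cohort.design[cfg["contrast"]].to_numpy()
    means = group_mean_ecm([r.centrality for r in results], groups)
    for g, vec in means.items():
        outputs.append(
            write_volume4d(insert_map(vec, mask), outdir / f"mean_ecm_group_{g}.nii")
        )
    curves = network_curves([r.timecourses for r in results], groups)
    rows = []
    for g in curves.means:
        for ki, name in enumerate(curves.names):
            for m in range(curves.means[g].shape[1]):
                rows.append(
                    {
                        "group": g,
                        "network": name,
                        "window": m,
                        "mean": curves.means[g][ki, m],
                        "ribbon": curves.ribbons[g][ki, m],
                    }
                )
    outputs.append(_write_tsv(pd.DataFrame(rows), outdir / "network_curves.tsv"))

    # -------------------------------------------------------------- manifest
    manifest = {
        "decm_version": __version__,
        "config": {k: v for k, v in cfg.items() if k != "subjects"},
        "window_lengths": window_lengths,
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return outdir
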