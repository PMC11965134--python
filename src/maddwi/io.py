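"""File formats, pipeline configuration, and the end-to-end run.

Conventions: DWI volumes and maps are NIfTI; b-value tables are single-line
whitespace-separated text in s/mm^2 (the de facto diffusion-toolkit
convention), with an optional sibling ``<btable>.nex`` file carrying the
per-b averaging counts; cohorts and comparison tables are CSV; ROC results
are JSON. Unfitted voxels are NaN in every map. Every run writes a manifest
with the seed, a config hash and the software version so outputs can be
re-created.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .classification import evaluate_parameters, roc_table
from .fitting import FitConfig, ParameterMaps, fit_volume
from .group_stats import (
    clinical_summary,
    comparisons_to_dataframe,
    summarize_comparisons,
)
from .model import BValueScheme, ValidationError
from .roi import CohortTable
from .synthetic import NoiseConfig, make_cohort

logger = logging.getLogger("maddwi")

__all__ = [
    "PipelineConfig",
    "read_dwi",
    "read_btable",
    "write_btable",
    "write_maps",
    "write_outputs",
    "run_pipeline",
]


@dataclasses.dataclass
class PipelineConfig:
    """Everything an end-to-end run needs; serializable to JSON."""

    mode: str = "simulate"  # "simulate" | "real"
    dwi_path: str | None = None
    btable_path: str | None = None
    mask_path: str | None = None
    labels_path: str | None = None
    output_dir: str = "maddwi_out"
    n_low: int = 30
    n_high: int = 24
    features: tuple[str, ...] = ("D_h", "f_r", "alpha_h")
    seed: int = 0
    fit: FitConfig = dataclasses.field(default_factory=FitConfig)
    noise: NoiseConfig = dataclasses.field(default_factory=NoiseConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["features"] = list(self.features)
        return d

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        fit = FitConfig(**raw.pop("fit", {}))
        noise = NoiseConfig(**raw.pop("noise", {}))
        raw["features"] = tuple(raw.get("features", ("D_h", "f_r", "alpha_h")))
        return cls(fit=fit, noise=noise, **raw)


def read_btable(path: str | Path) -> tuple[np.ndarray, np.ndarray | None]:
    """Read b-values (s/mm^2) and, if a ``<path>.nex`` sibling exists, NEX counts."""
    b = np.loadtxt(path, dtype=float).ravel()
    nex_path = Path(str(path) + ".nex")
    nex = np.loadtxt(nex_path, dtype=int).ravel() if nex_path.exists() else None
    return b, nex


def write_btable(path: str | Path, scheme: BValueScheme) -> None:
    """Write a scheme as s/mm^2 b-values plus a ``.nex`` averages sibling."""
    Path(path).write_text(" ".join(f"{b:g}" for b in scheme.to_smm2()) + "\n")
    Path(str(path) + ".nex").write_text(
        " ".join(str(n) for n in scheme.n_averages) + "\n"
    )


def read_dwi(
    nifti_path: str | Path, btable_path: str | Path
) -> tuple[np.ndarray, BValueScheme, np.ndarray]:
    """Load a 4D DWI volume with its b-table; returns (data, scheme, affine)."""
    img = nib.load(str(nifti_path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise ValidationError(f"{nifti_path}: expected a 4D volume, got {data.ndim}D")
    b_smm2, nex = read_btable(btable_path)
    if len(b_smm2) != data.shape[3]:
        raise ValidationError(
            f"b-table has {len(b_smm2)} entries but {nifti_path} has "
            f"{data.shape[3]} volumes"
        )
    scheme = BValueScheme.from_smm2(b_smm2, nex)
    return data, scheme, np.asarray(img.affine)


def write_maps(maps: ParameterMaps, out_dir: str | Path) -> list[Path]:
    """One NIfTI per fitted quantity, preserving the input affine.

    NaN marks voxels outside the mask or with failed fits; this is noted in
    each header's description field.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, grid in maps.maps.items():
        img = nib.Nifti1Image(grid.astype(np.float32), maps.affine)
        img.header["descrip"] = b"maddwi map; NaN = unfitted voxel"
        p = out / f"map_{name}.nii.gz"
        nib.save(img, str(p))
        written.append(p)
    return written


def write_outputs(
    output_dir: str | Path,
    config: PipelineConfig,
    maps: ParameterMaps | None = None,
    cohort: CohortTable | None = None,
    comparison_df: pd.DataFrame | None = None,
    roc_df: pd.DataFrame | None = None,
    clinical: dict | None = None,
) -> dict:
    """Write all artifacts and a manifest; returns the manifest dict."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    def _record(p: Path) -> None:
        files.append(str(p.relative_to(out)))

    if maps is not None:
        for p in write_maps(maps, out / "maps"):
            _record(p)
    if cohort is not None:
        p = out / "cohort.csv"
        cohort.to_dataframe().to_csv(p, index=False)
        _record(p)
    if comparison_df is not None:
        p = out / "group_comparison.csv"
        comparison_df.to_csv(p, index=False)
        _record(p)
    if roc_df is not None:
        p = out / "roc_results.json"
        p.write_text(json.dumps(roc_df.to_dict(orient="records"), indent=2))
        _record(p)
    if clinical is not None:
        p = out / "clinical_summary.json"
        p.write_text(json.dumps(clinical, indent=2))
        _record(p)

    cfg = config.to_dict()
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    manifest = {
        "software": "maddwi",
        "version": __version__,
        "seed": config.seed,
        "config": cfg,
        "config_hash": cfg_hash,
        "files": sorted(files),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def run_pipeline(config: PipelineConfig) -> dict:
    """End-to-end run: cohort -> group comparison -> ROC table -> outputs.

    Simulate mode draws a synthetic two-group cohort from the built-in
    grade distributions. Real mode reads a cohort CSV (``labels_path``) of
    per-subject ROI means produced by the fit/roi-stats stages. Returns a
    report dict with the comparison and ROC tables.
    """
    if config.mode == "simulate":
        cohort = make_cohort(config.n_low, config.n_high, seed=config.seed)
    elif config.mode == "real":
        if config.labels_path is None:
            raise ValidationError("real mode requires labels_path (cohort CSV)")
        cohort = CohortTable.from_dataframe(pd.read_csv(config.labels_path))
    else:
        raise ValidationError(f"unknown mode {config.mode!r}")

    logger.info("cohort: %d subjects (%s)", len(cohort), cohort.provenance)
    comparisons = summarize_comparisons(cohort)
    comparison_df = comparisons_to_dataframe(comparisons)
    significant = [
        r.parameter for r in comparisons
        if r.significant and r.parameter in ("ADC", "D_h", "f_r", "alpha_h")
    ]
    markers = significant or ["ADC", "D_h", "f_r", "alpha_h"]
    logger.info("ROC markers: %s + combined %s", markers, config.features)
    rocs = evaluate_parameters(cohort, parameters=markers, include_combined=True)
    roc_df = roc_table(rocs)

    manifest = write_outputs(
        config.output_dir, config, cohort=cohort,
        comparison_df=comparison_df, roc_df=roc_df,
    )
    return {
        "cohort_size": len(cohort),
        "comparisons": comparison_df,
        "roc": roc_df,
        "manifest": manifest,
    }
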