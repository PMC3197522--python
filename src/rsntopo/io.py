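"""Reading and writing of the standard on-disk formats.

Volumes and masks are NIfTI-1 (via nibabel, one mask per network so that
overlap is representable); nuisance regressors are TSV; configs are YAML;
result tables are TSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .pipeline import ResultsBundle
from .simulate import BoldDataset, GeneratorConfig, RSNAtlas

__all__ = [
    "write_dataset", "read_dataset", "write_atlas", "read_atlas",
    "write_config", "read_config", "write_bundle",
]

NUISANCE_COLUMNS = [f"mot{i}" for i in range(1, 7)] + ["wm", "ventricle", "global"]


def _affine(voxel_size_mm: float) -> np.ndarray:
    aff = np.diag([voxel_size_mm] * 3 + [1.0])
    return aff


def write_atlas(atlas: RSNAtlas, out_dir: str | Path,
                voxel_size_mm: float = 3.0) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, mask in atlas.masks.items():
        img = nib.Nifti1Image(mask.astype(np.uint8), _affine(voxel_size_mm))
        nib.save(img, out / f"mask-{name}.nii")
    (out / "atlas.json").write_text(json.dumps(
        dict(shape=list(atlas.shape), groups=atlas.groups), indent=2))


def read_atlas(in_dir: str | Path) -> RSNAtlas:
    src = Path(in_dir)
    meta = json.loads((src / "atlas.json").read_text())
    masks = {}
    for name in meta["groups"]:
        img = nib.load(src / f"mask-{name}.nii")
        masks[name] = np.asarray(img.dataobj).astype(bool)
    return RSNAtlas(shape=tuple(meta["shape"]), masks=masks,
                    groups=meta["groups"])


def write_dataset(ds: BoldDataset, out_dir: str | Path,
                  voxel_size_mm: float = 3.0) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(ds.volumes, _affine(voxel_size_mm))
    img.header.set_zooms((voxel_size_mm,) * 3 + (ds.tr,))
    nib.save(img, out / f"{ds.subject_id}_bold.nii")
    reg = pd.DataFrame(
        np.column_stack([ds.motion, ds.wm_signal, ds.ventricle_signal,
                         ds.global_signal]),
        columns=NUISANCE_COLUMNS)
    reg.to_csv(out / f"{ds.subject_id}_regressors.tsv", sep="\t", index=False)


def read_dataset(in_dir: str | Path, subject_id: str) -> BoldDataset:
    src = Path(in_dir)
    img = nib.load(src / f"{subject_id}_bold.nii")
    vol = np.asarray(img.dataobj, dtype=np.float32)
    tr = float(img.header.get_zooms()[3])
    reg = pd.read_csv(src / f"{subject_id}_regressors.tsv", sep="\t")
    return BoldDataset(
        subject_id=subject_id, volumes=vol, tr=tr,
        motion=reg[[f"mot{i}" for i in range(1, 7)]].to_numpy(),
        wm_signal=reg["wm"].to_numpy(),
        ventricle_signal=reg["ventricle"].to_numpy(),
        global_signal=reg["global"].to_numpy(),
    )


def write_config(config, path: str | Path) -> None:
    d = config.to_dict() if hasattr(config, "to_dict") else dataclasses.asdict(config)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def read_config(path: str | Path) -> GeneratorConfig:
    return GeneratorConfig.from_dict(yaml.safe_load(Path(path).read_text()))


def write_bundle(bundle: ResultsBundle, out_dir: str | Path) -> None:
    """Persist every result table as TSV plus a JSON provenance record."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.metrics_by_threshold.to_csv(
        out / "metrics_by_threshold.tsv", sep="\t", index=False)
    bundle.metrics_at_analysis_threshold.to_csv(
        out / "metrics_at_analysis_threshold.tsv", sep="\t", index=False)
    if bundle.equalized_metrics is not None:
        bundle.equalized_metrics.to_csv(
            out / "metrics_equalized.tsv", sep="\t", index=False)
    bundle.spectral_table.to_csv(out / "spectral.tsv", sep="\t", index=False)
    pd.DataFrame(bundle.cross_rsn.matrix,
                 index=bundle.cross_rsn.networks,
                 columns=bundle.cross_rsn.networks).to_csv(
        out / "cross_rsn_correlation.tsv", sep="\t")
    bundle.stats_report.to_csv(out / "stats_report.tsv", sep="\t", index=False)
    (out / "provenance.json").write_text(
        json.dumps(bundle.provenance, indent=2, default=str))
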