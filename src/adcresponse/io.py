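"""File formats: NIfTI volumes/masks, provenance-stamped CSV tables, YAML config."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .synthgen import ADCVolume, CohortConfig, TextureParams

__all__ = [
    "config_from_yaml",
    "config_hash",
    "config_to_yaml",
    "load_mask",
    "load_volume",
    "read_table",
    "save_mask",
    "save_volume",
    "write_table",
]


def _affine(spacing_mm) -> np.ndarray:
    return np.diag([spacing_mm[0], spacing_mm[1], spacing_mm[2], 1.0])


def save_volume(volume: ADCVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(volume.voxels.astype(np.float32), _affine(volume.spacing_mm))
    nib.save(img, str(path))


def load_volume(path: str | Path) -> ADCVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ADCVolume(np.asarray(img.dataobj, dtype=float), spacing)


def save_mask(mask: np.ndarray, spacing_mm, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.astype(np.uint8), _affine(spacing_mm))
    nib.save(img, str(path))


def load_mask(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0


def write_table(df: pd.DataFrame, path: str | Path, manifest_hash: str | None = None) -> None:
    """CSV with an optional provenance comment line carrying the manifest hash."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        if manifest_hash:
            fh.write(f"# manifest: {manifest_hash}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _config_dict(config: CohortConfig) -> dict:
    d = dataclasses.asdict(config)

    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        return obj

    return clean(d)


def config_to_yaml(config: CohortConfig, path: str | Path | None = None) -> str:
    text = yaml.safe_dump(_config_dict(config), sort_keys=True)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def config_from_yaml(path: str | Path) -> CohortConfig:
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if "texture" in data and isinstance(data["texture"], dict):
        data["texture"] = TextureParams(**data["texture"])
    for key in ("lesion_size_range_mm", "voxel_spacing_mm", "censor_range_months"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    for key in ("delta_params_by_group", "lrtr_confusion", "mrecist_probs"):
        if key in data and isinstance(data[key], dict):
            data[key] = {k: tuple(v) for k, v in data[key].items()}
    if isinstance(data.get("survival_hazards"), dict):
        data["survival_hazards"] = {k: tuple(v) for k, v in data["survival_hazards"].items()}
    config = CohortConfig(**data)
    config.validate()
    return config


def config_hash(config: CohortConfig) -> str:
    payload = json.dumps(_config_dict(config), sort_keys=True).encode("utf-8")
    return hashlib.sha256(payload).hexdigest()[:16]
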