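"""File I/O: NIfTI volumes, JSON sidecars, CSV cohort tables, YAML designs."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationModel, SodiumImage
from .cohort import CohortDesign, validate_cohort
from .phantom import RawSodiumVolume, TissueFractionMaps

__all__ = [
    "save_volume",
    "load_volume",
    "save_fractions",
    "load_fractions",
    "save_regions",
    "load_regions",
    "save_raw_volume",
    "load_raw_volume",
    "save_calibration",
    "load_calibration",
    "save_cohort",
    "load_cohort",
    "load_design",
    "save_design",
]


def save_volume(path, data: np.ndarray, affine: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))


def load_volume(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine


def save_fractions(prefix, fractions: TissueFractionMaps) -> None:
    """Write f_gm/f_wm/f_csf as <prefix>_{gm,wm,csf}.nii.gz."""
    prefix = str(prefix)
    for tag, f in (("gm", fractions.f_gm), ("wm", fractions.f_wm), ("csf", fractions.f_csf)):
        save_volume(f"{prefix}_{tag}.nii.gz", f, fractions.affine)


def load_fractions(gm_path, wm_path, csf_path) -> TissueFractionMaps:
    f_gm, affine = load_volume(gm_path)
    f_wm, a2 = load_volume(wm_path)
    f_csf, a3 = load_volume(csf_path)
    if not (np.allclose(affine, a2) and np.allclose(affine, a3)):
        raise ValueError("fraction maps disagree on the affine")
    maps = TissueFractionMaps(f_gm, f_wm, f_csf, affine)
    maps.validate(atol=1e-6)
    return maps


def _mask_to_indices(mask: np.ndarray) -> list[list[int]]:
    return np.argwhere(mask).astype(int).tolist()


def _indices_to_mask(indices, shape) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    if indices:
        idx = np.asarray(indices, dtype=int)
        m[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return m


def save_regions(path, volume: RawSodiumVolume) -> None:
    payload = {
        "shape": list(volume.signal.shape),
        "background": _mask_to_indices(volume.background_region),
        "eyes": [_mask_to_indices(m) for m in volume.eye_regions],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_regions(path, shape) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    with open(path) as fh:
        payload = json.load(fh)
    if list(shape) != payload["shape"]:
        raise ValueError(f"region file was written for grid {payload['shape']}, got {list(shape)}")
    bg = _indices_to_mask(payload["background"], shape)
    eyes = tuple(_indices_to_mask(e, shape) for e in payload["eyes"])
    return bg, eyes


def save_raw_volume(nifti_path, regions_path, volume: RawSodiumVolume) -> None:
    save_volume(nifti_path, volume.signal, volume.affine)
    save_regions(regions_path, volume)


def load_raw_volume(nifti_path, regions_path) -> RawSodiumVolume:
    signal, affine = load_volume(nifti_path)
    bg, eyes = load_regions(regions_path, signal.shape)
    vol = RawSodiumVolume(signal, affine, bg, eyes)
    vol.validate()
    return vol


def save_calibration(path, model: CalibrationModel) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=2, sort_keys=True)


def load_calibration(path) -> CalibrationModel:
    with open(path) as fh:
        return CalibrationModel(**json.load(fh))


def save_cohort(path, df: pd.DataFrame) -> None:
    validate_cohort(df)
    df.to_csv(path, index=False)


def load_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_cohort(df)
    return df


def load_design(path) -> CohortDesign:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    tuple_fields = {
        f.name for f in dataclasses.fields(CohortDesign)
        if "tuple" in str(f.type)
    }
    cfg = {k: tuple(v) if k in tuple_fields and isinstance(v, list) else v for k, v in cfg.items()}
    return CohortDesign(**cfg)


def save_design(path, design: CohortDesign) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(design), fh, sort_keys=True)
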