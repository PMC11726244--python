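"""NIfTI and tabular I/O.

Volumes are written with a diagonal affine built from ``spacing_mm`` and
``origin`` (array axes map directly to world axes; no reorientation is
attempted, which is adequate for phantom data and preprocessed inputs).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .types import ImageVolume, TumorMask

CLINICAL_COLUMNS = [
    "id",
    "site",
    "age_years",
    "sex",
    "resection",
    "chemo",
    "radiotherapy",
    "time_months",
    "event",
]


def _affine(spacing_mm, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    aff[:3, 3] = origin
    return aff


def write_nifti(vol: ImageVolume | TumorMask, path: str | Path) -> Path:
    path = Path(path)
    data = vol.voxels
    if isinstance(vol, TumorMask):
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(np.asarray(data), _affine(vol.spacing_mm, vol.origin))
    img.header.set_zooms(vol.spacing_mm)
    nib.save(img, str(path))
    return path


def read_nifti(path: str | Path, as_mask: bool = False) -> ImageVolume | TumorMask:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(o) for o in img.affine[:3, 3])
    if as_mask:
        return TumorMask((data > 0.5).astype(np.uint8), spacing, origin)
    return ImageVolume(np.asarray(data, dtype=np.float64), spacing, origin)


def write_clinical_csv(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    missing = [c for c in CLINICAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    table.to_csv(path, index=False)
    return path


def read_clinical_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    return df


def write_features_csv(subject_ids, features: np.ndarray, path: str | Path) -> Path:
    """Feature matrix (n_subjects x feature_dim) as a CSV with an id column."""
    features = np.asarray(features)
    cols = [f"f{i:04d}" for i in range(features.shape[1])]
    df = pd.DataFrame(features, columns=cols)
    df.insert(0, "subject_id", list(subject_ids))
    df.to_csv(path, index=False)
    return Path(path)


def read_features_csv(path: str | Path):
    df = pd.read_csv(path)
    ids = df["subject_id"].astype(str).tolist()
    feats = df.drop(columns=["subject_id"]).to_numpy(dtype=np.float64)
    return ids, feats


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))
    return path


def _json_default(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
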