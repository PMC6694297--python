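"""NIfTI / TSV / JSON round-trip helpers.

Volumes are stored X,Y,Z,T with a diagonal affine from the voxel size; the
cohort is assumed pre-registered to one grid, so analysis is grid-based.
Tables are tab-separated UTF-8 with a header row; manifests and subnetwork
assignments are JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "write_series", "read_series", "write_mask", "read_mask",
    "write_motion", "read_motion", "write_table", "read_table",
    "write_json", "read_json", "sha256_of",
]


def _affine(voxel_size_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size_mm
    return aff


def write_series(path, data_vt: np.ndarray, mask: np.ndarray,
                 voxel_size_mm: float = 1.0) -> None:
    """Write a (V, T) masked matrix as a 4D NIfTI on the mask's grid."""
    mask = np.asarray(mask, dtype=bool)
    vol = np.zeros(mask.shape + (data_vt.shape[1],), dtype=np.float32)
    vol[mask] = data_vt
    nib.save(nib.Nifti1Image(vol, _affine(voxel_size_mm)), str(path))


def read_series(path, mask: np.ndarray) -> np.ndarray:
    """Read a 4D NIfTI back to a (V, T) matrix over mask voxels."""
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj, dtype=np.float32)
    mask = np.asarray(mask, dtype=bool)
    if vol.shape[:3] != mask.shape:
        raise ValueError(
            f"{path}: grid {vol.shape[:3]} does not match mask {mask.shape}")
    return vol[mask]


def write_mask(path, mask: np.ndarray, voxel_size_mm: float = 1.0) -> None:
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8),
                             _affine(voxel_size_mm)), str(path))


def read_mask(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj) > 0


def write_motion(path, motion: np.ndarray) -> None:
    cols = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    pd.DataFrame(motion, columns=cols).to_csv(path, sep="\t", index=False)


def read_motion(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t").to_numpy(dtype=float)


def write_table(path, df: pd.DataFrame) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(path, obj) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def read_json(path):
    return json.loads(Path(path).read_text())


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
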