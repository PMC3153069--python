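"""NIfTI, CSV and JSON input/output.

Label volumes are stored as 16-bit integer NIfTI files (background 0);
masks as 0/1 integer volumes; tissue maps as three 3D files or one 4D
file with the channel order CSF, GM, WM. Voxel sizes always come from
the NIfTI header zooms — no isotropy assumption. A 4D file with a single
frame is accepted as 3D. Non-integer voxel data in a label file is a
format error, not silently rounded.

CSV reports use a fixed dialect (UTF-8, comma, header row, "." decimal)
so that re-runs with identical configuration produce byte-identical
files; a provenance comment line carrying the configuration hash is
written before the header and skipped on read.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .containers import BinaryMask, LabelVolume, TissueMaps

__all__ = [
    "FormatError",
    "read_label_volume",
    "write_label_volume",
    "read_mask",
    "write_mask",
    "read_tissue_maps",
    "write_tissue_maps",
    "write_report_csv",
    "read_report_csv",
]

_INT_TOL = 1e-6


class FormatError(ValueError):
    """File content violates the expected volume format."""


def _load_3d(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4:
        if data.shape[3] != 1:
            raise FormatError(f"{path}: expected 3D volume, got 4D with {data.shape[3]} frames")
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 3D volume, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise FormatError(f"{path}: invalid voxel spacing {zooms}")
    return data, tuple(float(z) for z in zooms)


def _check_integer(data: np.ndarray, path) -> np.ndarray:
    rounded = np.round(data)
    if np.abs(data - rounded).max(initial=0.0) > _INT_TOL:
        bad = float(data.ravel()[np.argmax(np.abs(data - rounded))])
        raise FormatError(f"{path}: non-integer voxel value {bad}")
    return rounded.astype(np.int16)


def read_label_volume(path, code_table_ref: str | None = None) -> LabelVolume:
    """Read an integer-coded 3D (or single-frame 4D) label map."""
    data, zooms = _load_3d(path)
    return LabelVolume(_check_integer(data, path), zooms, code_table_ref)


def write_label_volume(vol: LabelVolume, path) -> None:
    affine = np.diag(list(vol.voxel_size) + [1.0])
    img = nib.Nifti1Image(vol.grid.astype(np.int16), affine)
    img.header.set_zooms(vol.voxel_size)
    nib.save(img, str(path))


def read_mask(path) -> BinaryMask:
    data, zooms = _load_3d(path)
    data = _check_integer(data, path)
    if data.size and not np.isin(data, (0, 1)).all():
        raise FormatError(f"{path}: mask values must be 0/1")
    return BinaryMask(data.astype(bool), zooms)


def write_mask(mask: BinaryMask, path) -> None:
    affine = np.diag(list(mask.voxel_size) + [1.0])
    img = nib.Nifti1Image(mask.grid.astype(np.int16), affine)
    img.header.set_zooms(mask.voxel_size)
    nib.save(img, str(path))


def read_tissue_maps(path_or_paths) -> TissueMaps:
    """Read CSF/GM/WM maps from one 4D file or three 3D files."""
    if isinstance(path_or_paths, (list, tuple)):
        if len(path_or_paths) != 3:
            raise FormatError("expected exactly 3 tissue map files (CSF, GM, WM)")
        channels, zooms = [], None
        for p in path_or_paths:
            data, z = _load_3d(p)
            if zooms is not None and not np.allclose(z, zooms):
                raise FormatError("tissue map files have mismatched voxel spacing")
            zooms = z
            channels.append(data.astype(float))
        return TissueMaps(*channels, voxel_size=zooms)
    img = nib.load(str(path_or_paths))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4 or data.shape[3] != 3:
        raise FormatError(f"{path_or_paths}: expected 4D file with 3 frames (CSF, GM, WM)")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return TissueMaps(data[..., 0], data[..., 1], data[..., 2], voxel_size=zooms)


def write_tissue_maps(maps: TissueMaps, path) -> None:
    affine = np.diag(list(maps.voxel_size) + [1.0])
    stack = np.stack([maps.csf, maps.gm, maps.wm], axis=-1).astype(np.float32)
    img = nib.Nifti1Image(stack, affine)
    img.header.set_zooms(tuple(maps.voxel_size) + (1.0,))
    nib.save(img, str(path))


def write_report_csv(frame: pd.DataFrame, path, config_hash: str | None = None, index: bool = False) -> None:
    """Write a report table with an optional provenance comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        frame.to_csv(fh, index=index, lineterminator="\n")


def read_report_csv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)
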