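"""File I/O: NIfTI volumes, masks, ground-truth sidecars, and JSON reports."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .phantom import Image3D, VoxelGrid
from .quantify import RoiMask

__all__ = [
    "write_nifti",
    "read_image",
    "write_mask",
    "read_mask",
    "write_sidecar",
    "read_sidecar",
    "write_json_report",
]


def _affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.diag(list(grid.voxel_size_mm) + [1.0])
    return aff


def write_nifti(img: Image3D, path: str | Path) -> None:
    """Write a magnitude image as float32 NIfTI-1 with voxel size in the header."""
    nii = nib.Nifti1Image(img.values.astype(np.float32), _affine(img.grid))
    nii.header.set_zooms(img.grid.voxel_size_mm)
    nib.save(nii, str(path))


def read_image(path: str | Path) -> Image3D:
    """Read a 3D NIfTI magnitude image; voxel size comes from the header zooms."""
    nii = nib.load(str(path))
    data = np.asarray(nii.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    zooms = tuple(float(z) for z in nii.header.get_zooms()[:3])
    grid = VoxelGrid(dims=data.shape, voxel_size_mm=zooms)
    # magnitude images are nonnegative; clip tiny negative dtype artifacts
    return Image3D(grid, np.clip(data, 0.0, None))


def write_mask(mask: RoiMask, path: str | Path) -> None:
    nii = nib.Nifti1Image(mask.mask.astype(np.uint8), _affine(mask.grid))
    nii.header.set_zooms(mask.grid.voxel_size_mm)
    nib.save(nii, str(path))


def read_mask(path: str | Path, grid: VoxelGrid | None = None) -> RoiMask:
    """Read a binary mask; if ``grid`` is given, verify it matches the header."""
    nii = nib.load(str(path))
    data = np.asarray(nii.dataobj) > 0
    zooms = tuple(float(z) for z in nii.header.get_zooms()[:3])
    file_grid = VoxelGrid(dims=data.shape, voxel_size_mm=zooms)
    if grid is not None and file_grid != grid:
        raise ValueError(f"{path}: mask grid {file_grid} does not match image grid {grid}")
    return RoiMask(data, file_grid)


def write_sidecar(path: str | Path, payload: dict) -> None:
    """YAML sidecar with the phantom ground truth (counts, loading, C_ref, seed)."""
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def read_sidecar(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def write_json_report(path: str | Path, payload: dict) -> None:
    """Byte-stable JSON (sorted keys, trailing newline) for report files."""
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
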