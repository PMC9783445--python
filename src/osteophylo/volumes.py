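"""Voxel volume container and file I/O (TIFF stacks, NRRD).

The isotropic voxel size travels with the grid: TIFF stacks carry it in a
JSON sidecar (``<stem>.json`` with key ``voxel_size_mm``); NRRD carries it
in its header (read/written through SimpleITK when available).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["VoxelVolume", "read_volume", "write_volume"]


@dataclass
class VoxelVolume:
    """3D scalar grid with isotropic voxel size in mm.

    ``binary`` records whether the grid has already been thresholded
    (nonzero = bone).
    """

    grid: np.ndarray
    voxel_size: float
    binary: bool = False

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError("volume must be 3-dimensional")
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def bone_mask(self) -> np.ndarray:
        if not self.binary:
            raise ValueError("volume is not binary; binarize first")
        return self.grid > 0


def write_volume(volume: VoxelVolume, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, np.asarray(volume.grid))
        sidecar = path.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {"voxel_size_mm": volume.voxel_size, "binary": volume.binary}
            )
        )
    elif path.suffix.lower() == ".nrrd":
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.asarray(volume.grid))
        img.SetSpacing((volume.voxel_size,) * 3)
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unsupported volume format {path.suffix!r}")
    return path


def read_volume(path: str | Path, voxel_size: float | None = None) -> VoxelVolume:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        grid = tifffile.imread(path)
        binary = False
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            voxel_size = voxel_size or meta.get("voxel_size_mm")
            binary = bool(meta.get("binary", False))
        if voxel_size is None:
            raise ValueError(
                f"no voxel size: pass voxel_size or provide {sidecar.name}"
            )
        return VoxelVolume(grid, voxel_size, binary=binary)
    if path.suffix.lower() == ".nrrd":
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        spacing = img.GetSpacing()
        if max(spacing) - min(spacing) > 1e-9:
            raise ValueError("anisotropic NRRD voxels are not supported")
        grid = sitk.GetArrayFromImage(img)
        return VoxelVolume(grid, float(spacing[0]))
    raise ValueError(f"unsupported volume format {path.suffix!r}")
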