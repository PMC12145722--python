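"""NIfTI and tabular I/O.

Volumes are written as ``.nii.gz`` with the grid spacing/origin in the
affine.  The package's (LR, AP, SI) = (left+, posterior+, superior+) axes map
onto the NIfTI RAS+ world frame as (-R, -A, +S), i.e. an LPS-style affine.
Displacement fields are stored as 4D volumes with three components (mm).
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import nibabel as nib
import numpy as np

from .grid import DisplacementField, DoseGrid, LabelMap, ScalarImage, VoxelGrid

PathLike = Union[str, Path]


def _affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.diag([-grid.spacing[0], -grid.spacing[1], grid.spacing[2], 1.0])
    aff[0, 3] = -grid.origin[0]
    aff[1, 3] = -grid.origin[1]
    aff[2, 3] = grid.origin[2]
    return aff


def _grid_from_affine(aff: np.ndarray, shape) -> VoxelGrid:
    spacing = tuple(float(abs(aff[i, i])) for i in range(3))
    origin = (-float(aff[0, 3]), -float(aff[1, 3]), float(aff[2, 3]))
    return VoxelGrid(tuple(int(n) for n in shape[:3]), spacing, origin)


def save_volume(obj, path: PathLike) -> Path:
    """Write a ScalarImage/DoseGrid/LabelMap-mask/DisplacementField to NIfTI."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, ScalarImage):
        data, grid = obj.data, obj.grid
    elif isinstance(obj, DoseGrid):
        data, grid = obj.dose, obj.grid
    elif isinstance(obj, DisplacementField):
        data, grid = obj.vectors, obj.grid
    else:
        raise TypeError(f"cannot save object of type {type(obj)!r}")
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(grid))
    img.header.set_zooms(tuple(grid.spacing) + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, str(path))
    return path


def save_mask(mask: np.ndarray, grid: VoxelGrid, path: PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(mask.astype(np.uint8), _affine(grid))
    nib.save(img, str(path))
    return path


def load_image(path: PathLike) -> ScalarImage:
    img = nib.load(str(path))
    grid = _grid_from_affine(img.affine, img.shape)
    return ScalarImage(grid, np.asarray(img.dataobj, dtype=float))


def load_dose(path: PathLike) -> DoseGrid:
    img = nib.load(str(path))
    grid = _grid_from_affine(img.affine, img.shape)
    return DoseGrid(grid, np.asarray(img.dataobj, dtype=float))


def load_mask(path: PathLike) -> tuple[np.ndarray, VoxelGrid]:
    img = nib.load(str(path))
    grid = _grid_from_affine(img.affine, img.shape)
    return np.asarray(img.dataobj) > 0.5, grid


def load_field(path: PathLike) -> DisplacementField:
    img = nib.load(str(path))
    grid = _grid_from_affine(img.affine, img.shape)
    return DisplacementField(grid, np.asarray(img.dataobj, dtype=float))


def save_labels(labels: LabelMap, directory: PathLike, prefix: str = "") -> None:
    directory = Path(directory)
    for name in labels:
        save_mask(labels[name], labels.grid, directory / f"{prefix}{name}.nii.gz")


def load_labels(directory: PathLike, prefix: str = "") -> LabelMap:
    directory = Path(directory)
    masks = {}
    grid = None
    for path in sorted(directory.glob(f"{prefix}*.nii.gz")):
        name = path.name[len(prefix):].replace(".nii.gz", "")
        mask, grid = load_mask(path)
        masks[name] = mask
    if grid is None:
        raise FileNotFoundError(f"no masks under {directory}")
    return LabelMap(grid, masks)
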