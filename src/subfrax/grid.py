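"""Voxel grids and the image-like containers shared by every stage.

Coordinate convention (used everywhere in this package):

* array axes are ordered ``(LR, AP, SI)``;
* world coordinates are in millimetres, ``world = origin + index * spacing``;
* positive directions are patient-left, posterior, superior;
* voxel indices are 0-based.

All images, label maps, dose grids and displacement fields belonging to one
treatment session live on a single :class:`VoxelGrid`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, Tuple

import numpy as np

AXES = ("LR", "AP", "SI")

#: structures a label map may carry
STRUCTURES = ("gtv", "prostate", "ctv", "bladder", "rectum")


@dataclass(frozen=True)
class VoxelGrid:
    """Regular 3D voxel lattice with mm spacing.

    Parameters
    ----------
    shape
        Number of voxels along (LR, AP, SI); each axis must have >= 8.
    spacing
        Voxel size in mm per axis; strictly positive.
    origin
        World coordinate (mm) of voxel (0, 0, 0).
    """

    shape: Tuple[int, int, int]
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("grid shape/spacing/origin must be 3-vectors")
        if any(int(n) < 8 for n in self.shape):
            raise ValueError(f"grid needs >= 8 voxels per axis, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def spacing_arr(self) -> np.ndarray:
        return np.asarray(self.spacing, dtype=float)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_cm3(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def extent_mm(self) -> np.ndarray:
        """Physical size of the grid per axis in mm."""
        return np.asarray(self.shape) * self.spacing_arr

    def world_coordinates(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Meshgrid of world coordinates (mm), one array per axis."""
        axes = [
            self.origin[i] + np.arange(self.shape[i]) * self.spacing[i]
            for i in range(3)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij"))  # type: ignore[return-value]

    def same_geometry(self, other: "VoxelGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


def _check_grid(grid: VoxelGrid, data: np.ndarray, ncomp: int | None = None) -> np.ndarray:
    data = np.asarray(data)
    expected = tuple(grid.shape) + (() if ncomp is None else (ncomp,))
    if data.shape != expected:
        raise ValueError(f"data shape {data.shape} does not match grid {expected}")
    return data


@dataclass
class ScalarImage:
    """A scalar 3D image (arbitrary intensity units) on a :class:`VoxelGrid`."""

    grid: VoxelGrid
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = _check_grid(self.grid, self.data).astype(float, copy=False)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image intensities must be finite")

    def copy(self) -> "ScalarImage":
        return ScalarImage(self.grid, self.data.copy())


@dataclass
class DoseGrid:
    """Absorbed dose in Gy per voxel."""

    grid: VoxelGrid
    dose: np.ndarray

    def __post_init__(self) -> None:
        self.dose = _check_grid(self.grid, self.dose).astype(float, copy=False)
        if not np.all(np.isfinite(self.dose)):
            raise ValueError("dose must be finite")
        if self.dose.min() < -1e-9:
            raise ValueError("dose must be non-negative")
        np.clip(self.dose, 0.0, None, out=self.dose)

    def copy(self) -> "DoseGrid":
        return DoseGrid(self.grid, self.dose.copy())

    def __add__(self, other: "DoseGrid") -> "DoseGrid":
        if not self.grid.same_geometry(other.grid):
            raise ValueError("cannot add doses on different grids")
        return DoseGrid(self.grid, self.dose + other.dose)

    def __mul__(self, c: float) -> "DoseGrid":
        return DoseGrid(self.grid, self.dose * float(c))

    __rmul__ = __mul__


@dataclass
class DisplacementField:
    """Per-voxel displacement (mm) in pull-back convention.

    ``vectors[i, j, k]`` is the displacement added to the *fixed*-image world
    coordinate of voxel (i, j, k) to find the matching point in the moving
    image: ``warped(x) = moving(x + u(x))``.  For a structure translated by
    ``t`` from fixed to moving, the field over that structure equals ``t``.
    """

    grid: VoxelGrid
    vectors: np.ndarray
    converged: bool = True

    def __post_init__(self) -> None:
        self.vectors = _check_grid(self.grid, self.vectors, ncomp=3).astype(float, copy=False)
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement field must be finite")

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=-1)

    @classmethod
    def uniform(cls, grid: VoxelGrid, translation) -> "DisplacementField":
        """Field equal to one translation everywhere (rigid ground truth)."""
        t = np.asarray(translation, dtype=float)
        vec = np.broadcast_to(t, tuple(grid.shape) + (3,)).copy()
        return cls(grid, vec)

    @classmethod
    def zero(cls, grid: VoxelGrid) -> "DisplacementField":
        return cls(grid, np.zeros(tuple(grid.shape) + (3,)))


@dataclass
class LabelMap:
    """Binary organ masks on a shared grid.

    Holds any subset of :data:`STRUCTURES`.  Invariants enforced at
    construction: GTV inside CTV, CTV disjoint from bladder and rectum
    (when the masks involved are present).
    """

    grid: VoxelGrid
    masks: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, m in list(self.masks.items()):
            self.masks[name] = _check_grid(self.grid, m).astype(bool)
        self.validate()

    def validate(self) -> None:
        m = self.masks
        if "gtv" in m and "ctv" in m and np.any(m["gtv"] & ~m["ctv"]):
            raise ValueError("GTV must be contained in CTV")
        for oar in ("bladder", "rectum"):
            if "ctv" in m and oar in m and np.any(m["ctv"] & m[oar]):
                raise ValueError(f"CTV overlaps {oar}")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def __iter__(self) -> Iterator[str]:
        return iter(self.masks)

    def with_mask(self, name: str, mask: np.ndarray) -> "LabelMap":
        new = dict(self.masks)
        new[name] = mask
        return LabelMap(self.grid, new)

    def centroid_mm(self, name: str) -> np.ndarray:
        """World-coordinate centroid (mm) of a structure."""
        mask = self.masks[name]
        if not mask.any():
            raise ValueError(f"mask '{name}' is empty")
        idx = np.argwhere(mask)
        return np.asarray(self.grid.origin) + idx.mean(axis=0) * self.grid.spacing_arr

    def volume_cm3(self, name: str) -> float:
        return float(self.masks[name].sum()) * self.grid.voxel_volume_cm3

    def copy(self) -> "LabelMap":
        return LabelMap(self.grid, {k: v.copy() for k, v in self.masks.items()})
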