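"""Core spatial types: the shared analysis grid and images living on it.

All images in an analysis share one :class:`GridSpec` (the "template space"):
a regular axis-aligned voxel grid with a world origin in millimetres. Voxels
follow the half-open convention: voxel ``(i, j, k)`` is the box
``[origin + i*h, origin + (i+1)*h)`` per axis; a point lying exactly on a
shared face belongs to the higher-index voxel, so the boxes partition space
without double counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LESION_TYPES = ("cavity", "ce", "fet", "flair")


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned voxel grid in a shared template space.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels per axis; each entry must be >= 8.
    voxel_size_mm : tuple of float
        Voxel edge lengths in mm, strictly positive.
    space_id : str
        Label of the shared template space.
    origin_mm : tuple of float
        World coordinate (mm) of the corner of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    space_id: str = "synthetic-template"
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 8 for s in self.shape):
            raise ValueError(f"grid shape must be 3 entries, each >= 8; got {self.shape}")
        if len(self.voxel_size_mm) != 3 or any(h <= 0 for h in self.voxel_size_mm):
            raise ValueError(f"voxel sizes must be positive; got {self.voxel_size_mm}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size_mm", tuple(float(h) for h in self.voxel_size_mm))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    @property
    def affine(self) -> np.ndarray:
        """NIfTI-style affine mapping voxel *centers* to world mm."""
        a = np.eye(4)
        h = np.asarray(self.voxel_size_mm)
        a[:3, :3] = np.diag(h)
        a[:3, 3] = np.asarray(self.origin_mm) + h / 2.0
        return a

    def world_to_voxel(self, points_mm: np.ndarray) -> np.ndarray:
        """Continuous voxel coordinates (floor gives the containing voxel)."""
        p = np.atleast_2d(np.asarray(points_mm, dtype=float))
        return (p - np.asarray(self.origin_mm)) / np.asarray(self.voxel_size_mm)

    def voxel_centers_mm(self, indices: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return np.asarray(self.origin_mm) + (idx + 0.5) * np.asarray(self.voxel_size_mm)

    def extent_mm(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.asarray(self.origin_mm, dtype=float)
        hi = lo + np.asarray(self.shape) * np.asarray(self.voxel_size_mm)
        return lo, hi


def _check_values(grid: GridSpec, values: np.ndarray, what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != grid.shape:
        raise ValueError(f"{what} shape {arr.shape} does not match grid {grid.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{what} contains non-finite values")
    if np.any(arr < 0):
        raise ValueError(f"{what} contains negative values")
    return arr


@dataclass
class DensityImage:
    """Voxelwise fiber density (fibers/mm^3) on a grid.

    The value in a voxel is the number of distinct streamlines traversing it
    divided by the voxel volume (track-density convention).
    """

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = _check_values(self.grid, self.values, "fiber density")

    def same_grid(self, other) -> bool:
        return self.grid == other.grid


@dataclass
class TBRMap:
    """Tumor-to-brain ratio map (dimensionless amino-acid-PET uptake ratio)."""

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = _check_values(self.grid, self.values, "TBR")


@dataclass
class BinaryMask:
    """Binary lesion mask with its lesion type.

    lesion_type is one of "cavity" (resection cavity), "ce"
    (contrast-enhancing), "fet" (pathological FET-PET uptake, TBR > 1.6) or
    "flair" (T2/FLAIR hyperintensity).
    """

    grid: GridSpec
    values: np.ndarray
    lesion_type: str = "flair"

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.shape != self.grid.shape:
            raise ValueError(f"mask shape {arr.shape} does not match grid {self.grid.shape}")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be binary")
        if self.lesion_type not in LESION_TYPES:
            raise ValueError(f"unknown lesion type {self.lesion_type!r}; expected one of {LESION_TYPES}")
        self.values = arr.astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.grid.voxel_volume_mm3

    @property
    def volume_mL(self) -> float:
        return self.volume_mm3 / 1000.0


@dataclass
class StreamlineSet:
    """A tractogram: polylines in world mm coordinates.

    Each streamline is an (n, 3) float array with n >= 2 finite points.
    """

    streamlines: list = field(default_factory=list)

    def __post_init__(self) -> None:
        checked = []
        for i, s in enumerate(self.streamlines):
            arr = np.asarray(s, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 2:
                raise ValueError(f"streamline {i} must be an (n>=2, 3) point array")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"streamline {i} contains non-finite coordinates")
            checked.append(arr)
        self.streamlines = checked

    @property
    def count(self) -> int:
        return len(self.streamlines)

    def __len__(self) -> int:
        return self.count

    def __iter__(self):
        return iter(self.streamlines)
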