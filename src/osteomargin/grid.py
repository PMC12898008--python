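"""Voxel-grid primitives: grids with physical spacing, binary masks, ROI
cropping and resampling.

All geometry is expressed in a world frame measured in millimetres.  A grid is
an axis-aligned lattice of voxel *centers*: voxel ``(i, j, k)`` sits at
``origin + (i*sx, j*sy, k*sz)``.  Indices are 0-based; bounding boxes are
inclusive on both ends.  No axis flipping or reorientation is ever performed —
the world frame is whatever the mask header says it is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import EmptyForegroundError

__all__ = ["ImageGrid", "BinaryMask", "BoundingBox", "crop_roi", "paste", "resample"]

_TOL = 1e-6


@dataclass(frozen=True)
class ImageGrid:
    """A 3D voxel lattice with per-axis physical spacing (mm).

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along each axis ``(nx, ny, nz)``.
    spacing : tuple of float
        Physical distance (mm) between adjacent voxel centers per axis;
        strictly positive.
    origin : tuple of float
        World position (mm) of the center of voxel ``(0, 0, 0)``.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("ImageGrid is strictly three-dimensional")
        if any(n < 1 for n in self.shape):
            raise ValueError(f"grid shape must be >= 1 per axis, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    # -- coordinate transforms -------------------------------------------------
    def world(self, index: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of voxel indices, shape ``(..., 3)``."""
        index = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + index * np.asarray(self.spacing)

    def index(self, world: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel indices of world positions."""
        world = np.asarray(world, dtype=float)
        return (world - np.asarray(self.origin)) / np.asarray(self.spacing)

    def nearest_index(self, world: np.ndarray) -> np.ndarray:
        """Nearest voxel index of world positions, clipped to the grid."""
        idx = np.rint(self.index(world)).astype(np.int64)
        return np.clip(idx, 0, np.asarray(self.shape) - 1)

    # -- derived geometry ------------------------------------------------------
    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_diagonal(self) -> float:
        """Length (mm) of one voxel's body diagonal."""
        return float(math.sqrt(sum(s * s for s in self.spacing)))

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical span (mm) between first and last voxel centers, per axis."""
        return tuple((n - 1) * s for n, s in zip(self.shape, self.spacing))

    def all_centers(self) -> np.ndarray:
        """World coordinates of every voxel center, shape ``(*shape, 3)``."""
        axes = [o + s * np.arange(n) for o, s, n in zip(self.origin, self.spacing, self.shape)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)

    def isclose(self, other: "ImageGrid", tol: float = _TOL) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass
class BinaryMask:
    """Boolean occupancy on an :class:`ImageGrid` (tumor, bone, region...)."""

    grid: ImageGrid
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"mask values shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    @property
    def foreground_count(self) -> int:
        return int(self.values.sum())

    @property
    def is_empty(self) -> bool:
        return not self.values.any()

    def require_nonempty(self, what: str = "mask") -> None:
        if self.is_empty:
            raise EmptyForegroundError(f"{what} has empty foreground")

    def foreground_indices(self) -> np.ndarray:
        """Integer indices of foreground voxels, shape ``(n, 3)``."""
        return np.argwhere(self.values)

    def foreground_centers(self) -> np.ndarray:
        """World coordinates (mm) of foreground voxel centers, shape ``(n, 3)``."""
        return self.grid.world(self.foreground_indices())

    @property
    def volume_mm3(self) -> float:
        return self.foreground_count * self.grid.voxel_volume


@dataclass(frozen=True)
class BoundingBox:
    """Inclusive index box ``lo..hi`` on a parent grid.

    Maps crop indices back to the parent: crop voxel ``(0,0,0)`` is parent
    voxel ``lo``.
    """

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]
    grid: ImageGrid

    def __post_init__(self) -> None:
        object.__setattr__(self, "lo", tuple(int(v) for v in self.lo))
        object.__setattr__(self, "hi", tuple(int(v) for v in self.hi))
        for axis in range(3):
            if not (0 <= self.lo[axis] <= self.hi[axis] < self.grid.shape[axis]):
                raise ValueError(f"box {self.lo}..{self.hi} outside grid {self.grid.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(h - l + 1 for l, h in zip(self.lo, self.hi))

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h + 1) for l, h in zip(self.lo, self.hi))

    def crop_grid(self) -> ImageGrid:
        """Grid of the cropped subvolume (origin moved to voxel ``lo``)."""
        return ImageGrid(self.shape, self.grid.spacing, tuple(self.grid.world(self.lo)))


def tight_box(mask: BinaryMask) -> tuple[np.ndarray, np.ndarray]:
    """Componentwise min/max foreground index (the tight bounding box)."""
    mask.require_nonempty()
    idx = mask.foreground_indices()
    return idx.min(axis=0), idx.max(axis=0)


def crop_roi(mask: BinaryMask, pad_mm: float) -> tuple[BinaryMask, BoundingBox]:
    """Crop the region of interest around the mask foreground.

    The tight foreground bounding box is extended by ``ceil(pad_mm / spacing)``
    voxels per side (clipped to the grid), so the crop retains enough context
    for a margin expansion of up to ``pad_mm`` millimetres.

    Returns the cropped mask (with a correctly translated grid origin) and the
    :class:`BoundingBox` locating it on the parent grid.
    """
    if pad_mm < 0:
        raise ValueError(f"pad_mm must be >= 0, got {pad_mm}")
    mask.require_nonempty()
    lo, hi = tight_box(mask)
    pad_vox = np.array([math.ceil(pad_mm / s - 1e-12) for s in mask.grid.spacing], dtype=int)
    lo = np.maximum(lo - pad_vox, 0)
    hi = np.minimum(hi + pad_vox, np.asarray(mask.grid.shape) - 1)
    box = BoundingBox(tuple(lo), tuple(hi), mask.grid)
    sub = BinaryMask(box.crop_grid(), mask.values[box.slices].copy())
    return sub, box


def paste(sub: BinaryMask, box: BoundingBox) -> BinaryMask:
    """Paste a cropped mask back into a blank parent-grid mask."""
    if sub.values.shape != box.shape:
        raise ValueError("submask shape does not match box")
    values = np.zeros(box.grid.shape, dtype=bool)
    values[box.slices] = sub.values
    return BinaryMask(box.grid, values)


def resample(mask: BinaryMask, target_spacing) -> BinaryMask:
    """Resample a binary mask to a new per-axis spacing.

    The 0/1 indicator is interpolated trilinearly at the new voxel centers and
    thresholded at 0.5; exact ties map to foreground.  The output grid keeps
    the input origin (first voxel centers coincide) and is the smallest grid
    whose center span covers the input's physical extent.
    """
    target = tuple(float(t) for t in np.broadcast_to(np.asarray(target_spacing, float), (3,)))
    if any(t <= 0 for t in target):
        raise ValueError(f"target spacing must be positive, got {target}")
    src = mask.grid
    shape_out = tuple(
        int(math.ceil(e / t - 1e-9)) + 1 if e > 0 else 1 for e, t in zip(src.extent, target)
    )
    out_grid = ImageGrid(shape_out, target, src.origin)
    # output centers expressed in fractional input-index space
    axes = [t * np.arange(n) / s for n, t, s in zip(shape_out, target, src.spacing)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    vals = map_coordinates(
        mask.values.astype(np.float64), [gx, gy, gz], order=1, mode="constant", cval=0.0
    )
    return BinaryMask(out_grid, vals >= 0.5 - 1e-9)
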