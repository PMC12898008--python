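"""Synthetic tumor/bone phantoms with analytic ground truth.

Every pipeline stage is testable without clinical data: phantoms are simple
solids (sphere, ellipsoid, two-lobe, random blob) voxelized by the
voxel-*center* inclusion rule — a voxel is foreground iff its center lies in
the analytic solid — so closed-form volumes and margin-dilated volumes serve
as exact oracles.  The optional bone is a partial spherical shell (a crude
stand-in for cortical bone adjacent to the lesion), minus the tumor.

What these phantoms do *not* emulate: real pelvic anatomy, intensity data,
segmentation noise, or inter-annotator variability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .grid import BinaryMask, ImageGrid

__all__ = ["PhantomSpec", "BoneShellSpec", "PhantomTruth", "make_phantom"]

KINDS = ("sphere", "ellipsoid", "two_lobe", "blob")


@dataclass(frozen=True)
class BoneShellSpec:
    """Partial spherical shell: inner/outer radius (mm) and angular extent
    (radians) measured from the +z axis around ``center_mm``."""

    inner_radius_mm: float
    outer_radius_mm: float
    angular_extent_rad: float = math.pi
    center_mm: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.inner_radius_mm < self.outer_radius_mm:
            raise ValueError("need 0 < inner radius < outer radius")


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of a synthetic tumor (+ optional bone) pair.

    ``radii_mm`` is a scalar radius for ``sphere``, a semi-axis triple for
    ``ellipsoid``, and a per-lobe radius pair for ``two_lobe``; ``blob``
    ignores it and draws 3–7 overlapping ellipsoids from ``seed``.
    Centers default to the grid center.
    """

    kind: str
    grid: ImageGrid
    radii_mm: tuple | float = 8.0
    center_mm: tuple[float, float, float] | None = None
    centers_mm: tuple | None = None  # two_lobe: the two lobe centers
    bone: BoneShellSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")


@dataclass
class PhantomTruth:
    """Closed-form descriptors of the analytic tumor solid."""

    kind: str
    params: dict = field(default_factory=dict)
    volume_mm3: float | None = None

    def dilated_volume_mm3(self, margin_mm: float) -> float:
        """Exact volume of the solid dilated by a ball of radius ``margin``.

        Available for sphere and ellipsoid (Steiner formula); raises for the
        other kinds.
        """
        if self.kind == "sphere":
            r = self.params["radius_mm"] + margin_mm
            return 4.0 / 3.0 * math.pi * r**3
        if self.kind == "ellipsoid":
            a, b, c = self.params["radii_mm"]
            vol = 4.0 / 3.0 * math.pi * a * b * c
            area, mean_curv = _ellipsoid_steiner_coefficients(a, b, c)
            m = margin_mm
            return vol + area * m + mean_curv * m**2 + 4.0 / 3.0 * math.pi * m**3
        raise ValueError(f"no closed-form dilated volume for kind {self.kind!r}")


def _ellipsoid_steiner_coefficients(a: float, b: float, c: float, n: int = 600):
    """Surface area and integrated mean curvature of an ellipsoid.

    Computed by trapezoidal quadrature of the first/second fundamental forms
    over the standard spherical parameterization; accuracy far exceeds the
    percent-level tolerances these values are used at.
    """
    u = np.linspace(1e-6, math.pi - 1e-6, n)[:, None]
    v = np.linspace(0.0, 2.0 * math.pi, 2 * n)[None, :]
    su, cu, sv, cv = np.sin(u), np.cos(u), np.sin(v), np.cos(v)
    xu = np.stack([a * cu * cv, b * cu * sv, -c * su * np.ones_like(v)], axis=-1)
    xv = np.stack([-a * su * sv, b * su * cv, np.zeros(np.broadcast_shapes(u.shape, v.shape))], axis=-1)
    xuu = np.stack([-a * su * cv, -b * su * sv, -c * cu * np.ones_like(v)], axis=-1)
    xuv = np.stack([-a * cu * sv, b * cu * cv, np.zeros(np.broadcast_shapes(u.shape, v.shape))], axis=-1)
    xvv = np.stack([-a * su * cv, -b * su * sv, np.zeros(np.broadcast_shapes(u.shape, v.shape))], axis=-1)
    normal = np.cross(xu, xv)
    w = np.linalg.norm(normal, axis=-1)
    nhat = normal / w[..., None]
    E = np.einsum("...i,...i", xu, xu)
    F = np.einsum("...i,...i", xu, xv)
    G = np.einsum("...i,...i", xv, xv)
    L = np.einsum("...i,...i", xuu, nhat)
    M = np.einsum("...i,...i", xuv, nhat)
    N = np.einsum("...i,...i", xvv, nhat)
    H = np.abs(E * N - 2 * F * M + G * L) / (2 * (E * G - F**2))
    area = np.trapezoid(np.trapezoid(w, v[0], axis=1), u[:, 0])
    mean_curv = np.trapezoid(np.trapezoid(H * w, v[0], axis=1), u[:, 0])
    return float(area), float(mean_curv)


def _inside_ellipsoid(pts: np.ndarray, center: np.ndarray, radii: np.ndarray) -> np.ndarray:
    return (((pts - center) / radii) ** 2).sum(axis=-1) <= 1.0


def make_phantom(spec: PhantomSpec) -> tuple[BinaryMask, BinaryMask, PhantomTruth]:
    """Voxelize a phantom spec into (tumor, bone, truth).

    Bone is the shell solid minus the tumor (empty mask if no shell is
    specified).  Identical spec and seed produce bitwise-identical masks.
    """
    grid = spec.grid
    pts = grid.all_centers()
    center = np.asarray(
        spec.center_mm
        if spec.center_mm is not None
        else grid.world((np.asarray(grid.shape) - 1) / 2.0),
        dtype=float,
    )

    if spec.kind == "sphere":
        r = float(np.atleast_1d(spec.radii_mm)[0])
        tumor = ((pts - center) ** 2).sum(axis=-1) <= r**2
        truth = PhantomTruth("sphere", {"radius_mm": r, "center_mm": tuple(center)},
                             4.0 / 3.0 * math.pi * r**3)
    elif spec.kind == "ellipsoid":
        radii = np.broadcast_to(np.asarray(spec.radii_mm, float), (3,))
        tumor = _inside_ellipsoid(pts, center, radii)
        truth = PhantomTruth("ellipsoid", {"radii_mm": tuple(radii), "center_mm": tuple(center)},
                             4.0 / 3.0 * math.pi * float(np.prod(radii)))
    elif spec.kind == "two_lobe":
        r1, r2 = np.broadcast_to(np.asarray(spec.radii_mm, float).ravel(), (2,))
        if spec.centers_mm is not None:
            c1, c2 = (np.asarray(c, float) for c in spec.centers_mm)
        else:
            off = np.array([0.6 * (r1 + r2), 0.0, 0.0])
            c1, c2 = center - off / 2.0, center + off / 2.0
        tumor = (((pts - c1) ** 2).sum(axis=-1) <= r1**2) | (
            ((pts - c2) ** 2).sum(axis=-1) <= r2**2
        )
        truth = PhantomTruth(
            "two_lobe",
            {"radii_mm": (float(r1), float(r2)), "centers_mm": (tuple(c1), tuple(c2))},
            _two_sphere_union_volume(r1, r2, float(np.linalg.norm(c2 - c1))),
        )
    else:  # blob
        rng = np.random.default_rng(spec.seed)
        n_lobes = int(rng.integers(3, 8))
        tumor = np.zeros(grid.shape, dtype=bool)
        lobes = []
        # lobes cluster in the central ~fifth of the grid so phantoms retain
        # headroom for margin expansion and ROI padding
        span = 0.08 * min(grid.extent)
        for _ in range(n_lobes):
            c = center + rng.uniform(-span, span, size=3)
            radii = rng.uniform(0.04, 0.10, size=3) * min(grid.extent)
            tumor |= _inside_ellipsoid(pts, c, radii)
            lobes.append({"center_mm": tuple(c), "radii_mm": tuple(radii)})
        truth = PhantomTruth("blob", {"lobes": lobes, "seed": spec.seed}, None)

    _check_fits(tumor)
    bone = np.zeros(grid.shape, dtype=bool)
    if spec.bone is not None:
        bc = np.asarray(
            spec.bone.center_mm if spec.bone.center_mm is not None else center, float
        )
        rel = pts - bc
        rad = np.linalg.norm(rel, axis=-1)
        with np.errstate(invalid="ignore"):
            angle = np.arccos(np.clip(rel[..., 2] / np.maximum(rad, 1e-12), -1, 1))
        bone = (
            (rad >= spec.bone.inner_radius_mm)
            & (rad <= spec.bone.outer_radius_mm)
            & (angle <= spec.bone.angular_extent_rad)
            & ~tumor
        )
    return BinaryMask(grid, tumor), BinaryMask(grid, bone), truth


def _two_sphere_union_volume(r1: float, r2: float, d: float) -> float:
    v1 = 4.0 / 3.0 * math.pi * r1**3
    v2 = 4.0 / 3.0 * math.pi * r2**3
    if d >= r1 + r2:
        return v1 + v2
    if d <= abs(r1 - r2):
        return max(v1, v2)
    # lens (intersection) volume of two overlapping spheres
    lens = (
        math.pi
        * (r1 + r2 - d) ** 2
        * (d**2 + 2 * d * (r1 + r2) - 3 * (r1 - r2) ** 2)
        / (12 * d)
    )
    return v1 + v2 - lens


def _check_fits(tumor: np.ndarray) -> None:
    if not tumor.any():
        raise ValueError("phantom tumor is empty on this grid")
    edge = (
        tumor[0].any() or tumor[-1].any()
        or tumor[:, 0].any() or tumor[:, -1].any()
        or tumor[:, :, 0].any() or tumor[:, :, -1].any()
    )
    if edge:
        raise ValueError("phantom tumor touches the grid boundary; enlarge the grid")
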