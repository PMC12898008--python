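"""File formats and the end-to-end pipeline runner.

Masks travel as NIfTI (``.nii``/``.nii.gz``), stored 8-bit 0/1 with spacing
and origin taken from the header (diagonal, axis-aligned affines; no
reorientation is performed).  Surfaces export as binary STL or PLY, boundary
point clouds as PLY, osteotomy plans as JSON
(``{"planes": [{"name", "point", "normal"}, ...]}``), and run configuration
as YAML.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .errors import GridMismatchError
from .grid import BinaryMask, ImageGrid
from .region import MarginSpec, generate_dangerous_region
from .surface import Plane, plane_clearance, reconstruct_surface

__all__ = [
    "read_mask",
    "write_mask",
    "write_surface",
    "write_points_ply",
    "load_plan",
    "RunConfig",
    "run_pipeline",
]


def read_mask(path) -> BinaryMask:
    """Read a binary mask from NIfTI; spacing/origin come from the affine."""
    img = nib.load(str(path))
    affine = img.affine
    linear = affine[:3, :3]
    if not np.allclose(linear, np.diag(np.diag(linear)), atol=1e-6):
        raise GridMismatchError(
            "only axis-aligned (diagonal-affine) NIfTI masks are supported"
        )
    spacing = np.abs(np.diag(linear))
    data = np.asarray(img.dataobj)
    grid = ImageGrid(data.shape, tuple(spacing), tuple(affine[:3, 3]))
    return BinaryMask(grid, data > 0)


def write_mask(mask: BinaryMask, path) -> None:
    """Write a mask as 8-bit 0/1 NIfTI with a diagonal affine."""
    affine = np.eye(4)
    affine[:3, :3] = np.diag(mask.grid.spacing)
    affine[:3, 3] = mask.grid.origin
    img = nib.Nifti1Image(mask.values.astype(np.uint8), affine)
    nib.save(img, str(path))


def write_surface(surface, path) -> None:
    """Export a surface as STL (binary) or PLY, chosen by file extension."""
    surface.to_trimesh().export(str(path))


def write_points_ply(points: np.ndarray, path) -> None:
    import trimesh

    trimesh.PointCloud(np.asarray(points, dtype=float)).export(str(path))


def load_plan(path) -> list[Plane]:
    """Load osteotomy planes from a JSON plan file."""
    with open(path) as fh:
        doc = json.load(fh)
    planes = doc["planes"] if isinstance(doc, dict) else doc
    return [
        Plane(tuple(p["point"]), tuple(p["normal"]), p.get("name", f"plane_{i}"))
        for i, p in enumerate(planes)
    ]


@dataclass
class RunConfig:
    """Configuration of a full dangerous-region run."""

    tumor_path: str
    bone_path: str | None = None
    margin_mm: float = 20.0
    pad_mm: float | None = None
    dense_spacing: float | None = None
    band_mm: float | None = None
    shrink: float = 1.0
    restrict_to_bone: bool = False
    plan_path: str | None = None
    out_mask: str | None = None
    out_mesh: str | None = None
    out_report: str | None = None

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        doc.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**doc)

    def margin_spec(self) -> MarginSpec:
        return MarginSpec(
            margin_mm=self.margin_mm,
            band_mm=self.band_mm,
            pad_mm=self.pad_mm,
            dense_spacing=self.dense_spacing,
            restrict_to_bone=self.restrict_to_bone,
        )


def _round6(x) -> float:
    return float(np.round(float(x), 6))


def run_pipeline(config: RunConfig) -> dict:
    """Run crop → resample → transform → combine → surface, write outputs.

    Returns the machine-readable run report (also written to
    ``config.out_report`` if set).  Deterministic: identical inputs and
    config produce identical report fields.
    """
    tumor = read_mask(config.tumor_path)
    bone = read_mask(config.bone_path) if config.bone_path else None
    if bone is not None and not tumor.grid.isclose(bone.grid):
        raise GridMismatchError("tumor and bone grids do not match")
    spec = config.margin_spec()
    if config.dense_spacing is not None and any(
        config.dense_spacing > s + 1e-9 for s in tumor.grid.spacing
    ):
        raise ValueError("dense_spacing must not exceed the source spacing")

    region = generate_dangerous_region(tumor, bone, spec)
    surface = reconstruct_surface(region.boundary_points, shrink=config.shrink)

    report = {
        "config": {k: v for k, v in asdict(config).items()},
        "provenance": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in region.provenance.items()
        },
        "tumor_voxels": tumor.foreground_count,
        "tumor_volume_mm3": _round6(tumor.volume_mm3),
        "region_voxels": region.dense_mask.foreground_count,
        "region_volume_mm3": _round6(region.volume_mm3),
        "boundary_points": int(len(region.boundary_points)),
        "surface": {
            "vertices": surface.n_vertices,
            "faces": surface.n_faces,
            "watertight": surface.is_watertight,
            "area_mm2": _round6(surface.area),
            "volume_mm3": _round6(surface.volume),
        },
    }

    if config.plan_path:
        clearances = []
        for plane in load_plan(config.plan_path):
            c = plane_clearance(region, plane)
            clearances.append(
                {"name": plane.name, "clearance_mm": _round6(c),
                 "safe": bool(c >= 0.0)}
            )
        report["planes"] = clearances

    if config.out_mask:
        write_mask(region.dense_mask, config.out_mask)
    if config.out_mesh:
        write_surface(surface, config.out_mesh)
    if config.out_report:
        Path(config.out_report).write_text(json.dumps(report, indent=2) + "\n")
    return report
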