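import numpy as np
import pytest

from osteomargin import (
    BinaryMask,
    EmptyForegroundError,
    GridMismatchError,
    ImageGrid,
    MarginSpec,
    PadTooSmallError,
    adt,
    coarse_region,
    combine_regions,
    fine_ring,
    generate_dangerous_region,
    oracle_region,
)
from osteomargin.phantoms import PhantomSpec, make_phantom
from tests.conftest import random_blob_mask


def single_voxel_mask(grid_shape=(9, 9, 9), spacing=(1, 1, 1)):
    grid = ImageGrid(grid_shape, spacing)
    values = np.zeros(grid_shape, bool)
    values[tuple(s // 2 for s in grid_shape)] = True
    return BinaryMask(grid, values)


def enumerate_ball_count(spacing, margin):
    """Grid offsets within `margin` of the origin (independent enumeration)."""
    rng = [np.arange(-20, 21) * s for s in spacing]
    gx, gy, gz = np.meshgrid(*rng, indexing="ij")
    return int((gx**2 + gy**2 + gz**2 <= margin**2 + 1e-12).sum())


class TestCoarseRegion:
    def test_margin_zero_is_tumor(self):
        tumor = single_voxel_mask()
        region = coarse_region(adt(tumor), 0.0)
        assert np.array_equal(region.values, tumor.values)

    def test_single_voxel_margin_two_is_33_voxels(self):
        tumor = single_voxel_mask()
        region = coarse_region(adt(tumor), 2.0)
        assert region.foreground_count == enumerate_ball_count((1, 1, 1), 2.0) == 33

    @pytest.mark.parametrize("margin", [10.0, 15.0, 20.0])
    def test_cohort_margins_monotone(self, margin):
        tumor = single_voxel_mask((61, 61, 61))
        region = coarse_region(adt(tumor), margin)
        assert region.foreground_count == enumerate_ball_count((1, 1, 1), margin)


class TestFineRing:
    def test_zero_band_is_empty(self):
        dense = adt(single_voxel_mask(spacing=(0.5, 0.5, 0.5)))
        assert fine_ring(dense, 2.0, 0.0).foreground_count == 0

    def test_counts_match_direct_enumeration(self):
        # single-voxel tumor on a 0.5 mm grid; ring = distances in (1, 2]
        grid = ImageGrid((17, 17, 17), (0.5, 0.5, 0.5))
        values = np.zeros(grid.shape, bool)
        values[8, 8, 8] = True
        ring = fine_ring(adt(BinaryMask(grid, values)), 2.0, 1.0)
        expected = enumerate_ball_count((0.5, 0.5, 0.5), 2.0) - enumerate_ball_count(
            (0.5, 0.5, 0.5), 1.0
        )
        assert ring.foreground_count == expected

    def test_band_larger_than_margin_rejected(self):
        dense = adt(single_voxel_mask())
        with pytest.raises(ValueError):
            fine_ring(dense, 2.0, 3.0)


class TestMarginSpec:
    def test_band_default_is_source_voxel_diagonal(self):
        spec = MarginSpec(margin_mm=20.0).resolve(ImageGrid((4, 4, 4), (0.8, 0.8, 3.0)))
        assert spec.band_mm == pytest.approx(np.sqrt(0.64 + 0.64 + 9.0))
        assert spec.pad_mm == 40.0  # margin + 20
        assert spec.dense_spacing == pytest.approx((0.4, 0.4, 1.5))

    def test_pad_below_margin_rejected(self):
        with pytest.raises(ValueError):
            MarginSpec(margin_mm=10.0, pad_mm=5.0)


class TestCombine:
    def test_empty_ring_gives_coarse_upsampled(self):
        tumor = single_voxel_mask()
        coarse = coarse_region(adt(tumor), 2.0)
        dense_grid = ImageGrid((17, 17, 17), (0.5, 0.5, 0.5), tumor.grid.origin)
        ring = BinaryMask(dense_grid, np.zeros(dense_grid.shape, bool))
        spec = MarginSpec(margin_mm=2.0, band_mm=0.0, pad_mm=4.0)
        region = combine_regions(coarse, ring, spec)
        # nearest-upsample of the coarse mask, computed independently
        idx = dense_grid.all_centers().reshape(-1, 3)
        nearest = coarse.grid.nearest_index(idx)
        expected = coarse.values[tuple(nearest.T)].reshape(dense_grid.shape)
        assert np.array_equal(region.dense_mask.values, expected)

    def test_mismatched_world_extent_rejected(self):
        tumor = single_voxel_mask()
        coarse = coarse_region(adt(tumor), 2.0)
        far_grid = ImageGrid((17, 17, 17), (0.5, 0.5, 0.5), (100.0, 0.0, 0.0))
        ring = BinaryMask(far_grid, np.zeros(far_grid.shape, bool))
        with pytest.raises(GridMismatchError):
            combine_regions(coarse, ring, MarginSpec(2.0, band_mm=0.0, pad_mm=4.0))


class TestGeneratePipeline:
    def test_sphere_dilation_volume_and_containment(self, sphere_phantom):
        tumor, _, truth = sphere_phantom
        region = generate_dangerous_region(tumor, None, MarginSpec(margin_mm=20.0))
        exact = truth.dilated_volume_mm3(20.0)
        assert region.volume_mm3 == pytest.approx(exact, rel=0.03)
        dense = region.dense_mask
        idx = dense.grid.nearest_index(tumor.foreground_centers())
        assert dense.values[tuple(idx.T)].all()

    @pytest.mark.parametrize("seed", [0, 5])
    def test_blob_matches_oracle_outside_boundary_shell(self, seed):
        tumor = random_blob_mask(seed)
        spec = MarginSpec(margin_mm=4.0, pad_mm=7.0)
        region = generate_dangerous_region(tumor, None, spec)
        dense = region.dense_mask
        oracle = oracle_region(tumor, 4.0, dense.grid)
        d_true = _min_distance_to(tumor.foreground_centers(), dense.grid)
        shell = np.abs(d_true - 4.0) <= dense.grid.voxel_diagonal
        assert np.array_equal(dense.values[~shell], oracle.values[~shell])

    def test_translation_equivariance(self):
        tumor = random_blob_mask(2)
        spec = MarginSpec(margin_mm=3.0, pad_mm=5.0)
        a = generate_dangerous_region(tumor, None, spec)
        shifted = BinaryMask(
            ImageGrid(tumor.grid.shape, tumor.grid.spacing, (10.0, -4.0, 6.0)),
            tumor.values,
        )
        b = generate_dangerous_region(shifted, None, spec)
        assert np.array_equal(a.dense_mask.values, b.dense_mask.values)
        assert np.allclose(
            b.boundary_points - a.boundary_points, np.array([10.0, -4.0, 6.0])
        )

    def test_restrict_to_bone_clips_region(self):
        grid = ImageGrid((48, 48, 48), (1, 1, 1))
        tumor, bone, _ = make_phantom(
            PhantomSpec("sphere", grid, radii_mm=5.0,
                        bone=__import__("osteomargin").BoneShellSpec(7.0, 12.0))
        )
        spec = MarginSpec(margin_mm=6.0, pad_mm=9.0, restrict_to_bone=True)
        clipped = generate_dangerous_region(tumor, bone, spec)
        free = generate_dangerous_region(
            tumor, bone, MarginSpec(margin_mm=6.0, pad_mm=9.0)
        )
        assert clipped.dense_mask.foreground_count < free.dense_mask.foreground_count
        assert not (clipped.dense_mask.values & ~free.dense_mask.values).any()

    def test_errors(self):
        grid = ImageGrid((20, 20, 20), (1, 1, 1))
        empty = BinaryMask(grid, np.zeros(grid.shape, bool))
        with pytest.raises(EmptyForegroundError):
            generate_dangerous_region(empty, None, MarginSpec(margin_mm=5.0))
        # tumor near the grid edge: padding gets clipped away entirely
        edge = np.zeros(grid.shape, bool)
        edge[0:3, 9:12, 9:12] = True
        with pytest.raises(PadTooSmallError):
            generate_dangerous_region(BinaryMask(grid, edge), None,
                                      MarginSpec(margin_mm=8.0, pad_mm=8.0))
        other = BinaryMask(ImageGrid(grid.shape, (2, 1, 1)), np.zeros(grid.shape, bool))
        tum = np.zeros(grid.shape, bool)
        tum[10, 10, 10] = True
        with pytest.raises(GridMismatchError):
            generate_dangerous_region(BinaryMask(grid, tum), other,
                                      MarginSpec(margin_mm=3.0, pad_mm=5.0))


class TestOracleRegion:
    def test_margin_zero_recovers_tumor(self):
        tumor = random_blob_mask(4)
        out = oracle_region(tumor, 0.0, tumor.grid)
        assert np.array_equal(out.values, tumor.values)

    def test_single_voxel_ball(self):
        tumor = single_voxel_mask()
        out = oracle_region(tumor, 2.0, tumor.grid)
        assert out.foreground_count == 33

    @pytest.mark.parametrize("seed", range(4))
    def test_agrees_with_adt_threshold(self, seed):
        tumor = random_blob_mask(seed, side=14)
        margin = 3.5
        via_adt = adt(tumor).values <= margin + 1e-9
        assert np.array_equal(
            oracle_region(tumor, margin, tumor.grid).values, via_adt
        )


def _min_distance_to(sources: np.ndarray, grid: ImageGrid) -> np.ndarray:
    """Exact min distance from every grid voxel center to the source points."""
    targets = grid.all_centers().reshape(-1, 3)
    out = np.empty(len(targets))
    chunk = max(1, int(4e6 // max(len(sources), 1)))
    for s in range(0, len(targets), chunk):
        d2 = ((targets[s : s + chunk, None, :] - sources[None]) ** 2).sum(axis=2)
        out[s : s + chunk] = np.sqrt(d2.min(axis=1))
    return out.reshape(grid.shape)
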