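import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osteomargin import (
    BinaryMask,
    EmptyForegroundError,
    ImageGrid,
    crop_roi,
    paste,
    resample,
)
from tests.conftest import random_mask

spacing_st = st.tuples(*[st.floats(0.3, 5.0) for _ in range(3)])
origin_st = st.tuples(*[st.floats(-100.0, 100.0) for _ in range(3)])


class TestImageGrid:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(spacing=spacing_st, origin=origin_st)
    def test_index_world_round_trip(self, spacing, origin):
        grid = ImageGrid((7, 5, 9), spacing, origin)
        idx = np.argwhere(np.ones(grid.shape, bool))
        back = grid.index(grid.world(idx))
        assert np.allclose(back, idx, atol=1e-7)

    def test_rejects_nonpositive_spacing(self):
        with pytest.raises(ValueError):
            ImageGrid((4, 4, 4), (1.0, 0.0, 1.0))

    def test_voxel_diagonal(self):
        grid = ImageGrid((2, 2, 2), (0.8, 0.8, 3.0))
        assert grid.voxel_diagonal == pytest.approx(np.sqrt(0.64 + 0.64 + 9.0))


class TestCropRoi:
    def test_single_voxel_tight_box(self):
        values = np.zeros((11, 11, 11), bool)
        values[5, 5, 5] = True
        mask = BinaryMask(ImageGrid((11, 11, 11), (1, 1, 1)), values)
        sub, box = crop_roi(mask, 0.0)
        assert box.lo == (5, 5, 5) and box.hi == (5, 5, 5)
        assert sub.grid.shape == (1, 1, 1) and sub.values.all()
        assert np.allclose(sub.grid.origin, (5, 5, 5))

    def test_padded_sphere_span_matches_brute_force(self):
        # sphere radius 5 mm centered in a 60^3 1 mm grid, pad 22 mm
        grid = ImageGrid((60, 60, 60), (1, 1, 1))
        pts = grid.all_centers()
        center = grid.world((30, 30, 30))
        mask = BinaryMask(grid, ((pts - center) ** 2).sum(axis=-1) <= 25.0)
        _, box = crop_roi(mask, 22.0)
        idx = mask.foreground_indices()
        lo_b, hi_b = idx.min(axis=0), idx.max(axis=0)
        assert box.shape == (55, 55, 55)  # 11-voxel diameter + 22 per side
        assert np.array_equal(np.asarray(box.lo), lo_b - 22)
        assert np.array_equal(np.asarray(box.hi), hi_b + 22)

    @pytest.mark.parametrize("seed", range(5))
    def test_crop_then_paste_is_lossless(self, seed):
        mask = random_mask(seed)
        sub, box = crop_roi(mask, 3.7)
        restored = paste(sub, box)
        assert np.array_equal(restored.values, mask.values)

    def test_crop_clips_to_grid_bounds(self):
        values = np.zeros((8, 8, 8), bool)
        values[1, 1, 1] = True
        mask = BinaryMask(ImageGrid((8, 8, 8), (1, 1, 1)), values)
        _, box = crop_roi(mask, 50.0)
        assert box.lo == (0, 0, 0) and box.hi == (7, 7, 7)

    def test_errors(self):
        empty = BinaryMask(ImageGrid((4, 4, 4), (1, 1, 1)), np.zeros((4, 4, 4), bool))
        with pytest.raises(EmptyForegroundError):
            crop_roi(empty, 1.0)
        full = BinaryMask(ImageGrid((4, 4, 4), (1, 1, 1)), np.ones((4, 4, 4), bool))
        with pytest.raises(ValueError):
            crop_roi(full, -1.0)


class TestResample:
    def test_identity_at_same_spacing(self):
        mask = random_mask(3)
        out = resample(mask, mask.grid.spacing)
        assert out.grid.isclose(mask.grid)
        assert np.array_equal(out.values, mask.values)

    def test_solid_cube_against_analytic_interpolation(self):
        # 2x2x2-voxel solid cube at 2 mm spacing -> 1 mm.  For a separable
        # (outer-product) indicator, trilinear interpolation factorizes into
        # per-axis linear weights, so the expected field has a closed form:
        # w(x) ramps 0 -> 1 over [input center - spacing, input center].
        grid = ImageGrid((6, 6, 6), (2, 2, 2))
        values = np.zeros((6, 6, 6), bool)
        values[2:4, 2:4, 2:4] = True
        out = resample(BinaryMask(grid, values), 1.0)
        x = np.arange(11) * 1.0  # output voxel centers, mm
        w = np.interp(x, [2.0, 4.0, 6.0, 8.0], [0.0, 1.0, 1.0, 0.0])
        expected = np.einsum("i,j,k->ijk", w, w, w) >= 0.5 - 1e-9
        assert np.array_equal(out.values, expected)
        # interior centers survive; the 0.5 level set passes through the
        # physical cube faces (face-center columns included, corners chamfered)
        assert out.foreground_count == expected.sum() == 81

    def test_anisotropic_ct_spacing_to_isotropic(self):
        rng = np.random.default_rng(7)
        grid = ImageGrid((14, 14, 8), (0.8, 0.8, 3.0))
        values = np.zeros(grid.shape, bool)
        values[4:10, 4:10, 2:6] = True
        mask = BinaryMask(grid, values)
        out = resample(mask, (1.0, 1.0, 1.0))
        # world-extent covered; centroid preserved within one output diagonal
        assert all(
            (n - 1) * t >= e - 1e-9
            for n, t, e in zip(out.grid.shape, out.grid.spacing, grid.extent)
        )
        c_in = mask.foreground_centers().mean(axis=0)
        c_out = out.foreground_centers().mean(axis=0)
        assert np.linalg.norm(c_in - c_out) < out.grid.voxel_diagonal

    @pytest.mark.parametrize("seed", range(4))
    def test_translation_equivariance(self, seed):
        mask = random_mask(seed, max_side=12)
        shift = np.array([5.0, -3.0, 11.0])
        shifted = BinaryMask(
            ImageGrid(mask.grid.shape, mask.grid.spacing, tuple(shift)), mask.values
        )
        a = resample(mask, 1.0)
        b = resample(shifted, 1.0)
        assert np.allclose(np.asarray(b.grid.origin) - np.asarray(a.grid.origin), shift)
        assert np.array_equal(a.values, b.values)

    def test_finer_spacing_keeps_interior_voxels(self):
        # input foreground voxels whose centers sit well inside the solid
        # must survive refinement
        grid = ImageGrid((10, 10, 10), (2, 2, 2))
        values = np.zeros(grid.shape, bool)
        values[3:7, 3:7, 3:7] = True
        mask = BinaryMask(grid, values)
        out = resample(mask, (0.7, 0.9, 1.1))
        inner = BinaryMask(grid, np.zeros(grid.shape, bool))
        inner.values[4:6, 4:6, 4:6] = True
        idx = out.grid.nearest_index(inner.foreground_centers())
        assert out.values[tuple(idx.T)].all()

    def test_rejects_nonpositive_target(self):
        mask = random_mask(1)
        with pytest.raises(ValueError):
            resample(mask, (1.0, -0.5, 1.0))
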