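import numpy as np
import pytest

from osteomargin import BinaryMask, ImageGrid


def brute_force_distance_map(mask: BinaryMask) -> np.ndarray:
    """All-pairs minimum world distance to foreground centers (test oracle)."""
    targets = mask.grid.all_centers().reshape(-1, 3)
    sources = mask.foreground_centers()
    out = np.empty(len(targets))
    chunk = max(1, int(4e6 // max(len(sources), 1)))
    for s in range(0, len(targets), chunk):
        d2 = ((targets[s : s + chunk, None, :] - sources[None]) ** 2).sum(axis=2)
        out[s : s + chunk] = np.sqrt(d2.min(axis=1))
    return out.reshape(mask.grid.shape)


def random_mask(seed: int, max_side: int = 20, density: float = 0.05) -> BinaryMask:
    """Seeded random mask on a random anisotropic grid, nonempty."""
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in rng.integers(6, max_side + 1, size=3))
    spacing = tuple(float(s) for s in rng.uniform(0.6, 3.0, size=3))
    values = rng.random(shape) < density
    if not values.any():
        values[tuple(d // 2 for d in shape)] = True
    return BinaryMask(ImageGrid(shape, spacing), values)


def random_blob_mask(seed: int, side: int = 26, spacing=(1.0, 1.0, 2.0)) -> BinaryMask:
    """Seeded connected blob (random ellipsoid union) with border headroom."""
    rng = np.random.default_rng(seed)
    grid = ImageGrid((side,) * 3, spacing)
    pts = grid.all_centers()
    center = grid.world((np.asarray(grid.shape) - 1) / 2.0)
    values = np.zeros(grid.shape, dtype=bool)
    for _ in range(rng.integers(1, 4)):
        c = center + rng.uniform(-1.5, 1.5, size=3)
        radii = rng.uniform(1.5, 3.0, size=3)
        values |= (((pts - c) / radii) ** 2).sum(axis=-1) <= 1.0
    return BinaryMask(grid, values)


@pytest.fixture
def sphere_phantom():
    from osteomargin.phantoms import PhantomSpec, make_phantom

    grid = ImageGrid((64, 64, 64), (1.0, 1.0, 1.0))
    return make_phantom(PhantomSpec("sphere", grid, radii_mm=8.0))
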