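import numpy as np
import pytest
from hypothesis import settings

from gliorad.features.quantize import QuantizedROI

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_qroi(levels, spacing=(1.0, 1.0, 1.0), bins=None):
    """Build a QuantizedROI directly from an explicit level grid.

    Zero entries are outside the ROI; positive entries are gray levels.
    """
    levels = np.asarray(levels, dtype=np.int64)
    if levels.ndim < 3:
        levels = levels.reshape(levels.shape + (1,) * (3 - levels.ndim))
    mask = levels > 0
    if bins is None:
        bins = int(levels.max())
    return QuantizedROI(
        levels=levels,
        mask=mask,
        values=levels.astype(float),
        spacing=spacing,
        bins=bins,
    )


@pytest.fixture(scope="session")
def small_phantom_study():
    """One default-condition phantom subject (shared: extraction is ~1 s)."""
    from gliorad import PhantomSpec, simulate_study

    return simulate_study(PhantomSpec(n_subjects=2, seed=7), 0)


@pytest.fixture(scope="session")
def planted_dataset():
    from gliorad import TabularSpec, simulate_feature_matrix

    return simulate_feature_matrix(TabularSpec(seed=42))


def random_test_volumes(n_per_shape=6, seed=1234):
    """Random integer level grids (with embedded masks) up to 4x4x4."""
    rng = np.random.default_rng(seed)
    shapes = [(2, 2, 2), (3, 3, 3), (4, 4, 4), (1, 4, 1), (4, 4, 1), (2, 3, 4)]
    vols = []
    for shape in shapes:
        for _ in range(n_per_shape):
            levels = rng.integers(1, 5, size=shape)
            # random mask holes, but keep at least 2 voxels
            hole = rng.random(shape) < 0.2
            levels = np.where(hole, 0, levels)
            if (levels > 0).sum() < 2:
                levels.flat[:2] = 1
            vols.append(levels)
    return vols
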