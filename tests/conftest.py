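import numpy as np
import pytest

from petstab import LesionMask, PetVolume


def digitized_sphere(radius_voxels: float, spacing=(1.0, 1.0, 1.0), margin=3):
    """Digitized ball mask centered on an odd grid."""
    half = int(np.ceil(radius_voxels)) + margin
    n = 2 * half + 1
    g = np.arange(n) - half
    x, y, z = np.meshgrid(g, g, g, indexing="ij")
    ind = (x**2 + y**2 + z**2) <= radius_voxels**2
    return LesionMask(indicator=ind, spacing=spacing)


def random_volume_and_mask(rng, shape=(4, 4, 4), n_levels=4, spacing=(1.0, 1.0, 1.0)):
    """Small random SUV volume with a random nonempty mask."""
    values = rng.integers(0, n_levels, size=shape).astype(float) * 0.25 + 0.1
    mask = rng.random(shape) < 0.6
    if not mask.any():
        mask[tuple(d // 2 for d in shape)] = True
    return (
        PetVolume(values=values, spacing=spacing),
        LesionMask(indicator=mask, spacing=spacing),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def sphere_mask_r12():
    return digitized_sphere(12.0)
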