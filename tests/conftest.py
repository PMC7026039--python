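"""Shared fixtures: small synthetic images used across the suite."""

import numpy as np
import pytest
from scipy import ndimage

from atlasforge.image_core import Volume
from atlasforge.phantoms import PhantomSpec, make_phantom


def smooth_disk(shape, center, radius, value=100.0, sigma=1.0):
    """Softened disk/sphere test object (2D or 3D)."""
    idx = np.indices(shape, dtype=float)
    rho = np.sqrt(sum((idx[i] - center[i]) ** 2 for i in range(len(shape))))
    img = (rho <= radius).astype(float) * value
    return ndimage.gaussian_filter(img, sigma)


def gaussian_bump_field(shape, amplitude=2.0, sigma=None, axis=0):
    """Smooth displacement field: Gaussian bump along one axis."""
    ndim = len(shape)
    if sigma is None:
        sigma = min(shape) / 6.0
    idx = np.indices(shape, dtype=float)
    c = (np.asarray(shape) - 1.0) / 2.0
    r2 = sum((idx[i] - c[i]) ** 2 for i in range(ndim))
    bump = amplitude * np.exp(-r2 / (2.0 * sigma**2))
    field = np.zeros((*shape, ndim))
    field[..., axis] = bump
    return field


@pytest.fixture(scope="session")
def mr_phantom():
    spec = PhantomSpec(
        grid_shape=(48, 48, 48), modality="MR", brain_radii=(16.0, 18.0, 15.0), seed=11
    )
    return make_phantom(spec)


@pytest.fixture(scope="session")
def ct_phantom():
    spec = PhantomSpec(
        grid_shape=(48, 48, 32), modality="CT", brain_radii=(16.0, 18.0, 12.0), seed=7
    )
    return make_phantom(spec)


@pytest.fixture()
def small_volume():
    rng = np.random.default_rng(5)
    return Volume(rng.normal(50, 10, size=(16, 16, 16)).astype(np.float32))
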