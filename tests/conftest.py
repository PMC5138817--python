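import numpy as np
import pytest

import ctradiomics as cr


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_sphere_phantom(noise_sd: float, seed: int = 0, radius: float = 10.0,
                        contrast: float = 60.0, shape=(40, 40, 40)):
    """High-contrast sphere on zero background with i.i.d. Gaussian noise."""
    g = np.random.default_rng(seed)
    zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]]
    c = (np.array(shape) - 1) / 2
    mask = ((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2) <= radius**2
    img = np.where(mask, contrast, 0.0)
    if noise_sd > 0:
        img = img + g.normal(0.0, noise_sd, shape)
    return cr.ImageVolume(img), cr.ROIMask(mask)


@pytest.fixture
def sphere_phantom():
    return make_sphere_phantom


@pytest.fixture
def small_design():
    return cr.CohortDesign(
        n_patients=6,
        seed=7,
        image_shape=(32, 32, 32),
        tumor_radius_range=(6.0, 8.0),
        texture_corr_length_by_class={"A": 1.0, "B": 3.0},
        class_probs={"A": 0.5, "B": 0.5},
    )
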