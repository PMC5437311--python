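import numpy as np
import pytest

from sagakit import synthetic_data as sd


@pytest.fixture(scope="session")
def small_phantom():
    """A 6-frame, 5-branch phantom with mild noise, plus its analytic truth."""
    spec = sd.SpheroidPhantomSpec(
        image_shape=(6, 6, 128, 128), core_radius=14, n_branches=5,
        branch_growth_rate=6, branch_width=5, fg_intensity=100,
        bg_intensity=10, noise_sd=0.8, seed=7)
    stack, truth = sd.generate_spheroid_stack(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless phantom for segmentation-oracle checks."""
    spec = sd.SpheroidPhantomSpec(
        image_shape=(4, 6, 96, 96), core_radius=14, n_branches=4,
        branch_growth_rate=5, branch_width=5, noise_sd=0.0, seed=3)
    stack, truth = sd.generate_spheroid_stack(spec)
    return spec, stack, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def disk_mask(shape, center, radius):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2
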