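import numpy as np
import pytest

from beanspec.components import build_component_library, default_band_grid
from beanspec.hypercube import calibrate_reflectance, to_absorbance
from beanspec.synthetic import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def lib256():
    """Full-resolution component library on the 256-band instrument grid."""
    return build_component_library(default_band_grid())


@pytest.fixture(scope="session")
def lib64():
    """Coarse 64-band library for fast image-level tests."""
    return build_component_library(default_band_grid(64))


def clean_scene_spec(**overrides):
    """SceneSpec with every stochastic degradation switched off."""
    base = dict(rows=100, cols=120, n_beans=4, noise_sd=0.0,
                scatter_slope_sd=0.0, scatter_offset_sd=0.0, ref_noise_sd=0.0,
                seed=5)
    base.update(overrides)
    return SceneSpec(**base)


@pytest.fixture(scope="session")
def noiseless_scene(lib64):
    """(cube, white, dark, truth) with no noise or scatter, 64 bands."""
    return generate_scene(clean_scene_spec(), lib64)


@pytest.fixture(scope="session")
def noiseless_absorbance(noiseless_scene):
    cube, white, dark, truth = noiseless_scene
    return to_absorbance(calibrate_reflectance(cube, white, dark)), truth
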