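"""Shared fixtures: small phantoms and cohorts kept cheap for unit tests."""

import numpy as np
import pytest

from habitatrx.config import ClinicalSpec, HabitatTexture, PhantomSpec
from habitatrx.synthetic import generate_phantom


def small_phantom_spec(**overrides) -> PhantomSpec:
    """A shrunken phantom (same structure, ~500-voxel lesions) for fast tests."""
    base = dict(
        image_shape=(40, 40, 18),
        spacing=(1.0, 1.0, 3.0),
        lesion_halfaxis_xy=(6.0, 8.0),
        lesion_halfaxis_z=(3.0, 4.0),
    )
    base.update(overrides)
    return PhantomSpec(**base)


def noiseless_spec(**overrides) -> PhantomSpec:
    """Deterministic piecewise-constant phantom: each habitat at its mean."""
    tiny = 1e-12
    base = dict(
        adc_textures=tuple(
            HabitatTexture(mean=m, variance=tiny, corr_len=1.0)
            for m in (800.0, 1100.0, 1400.0)
        ),
        t2_textures=tuple(
            HabitatTexture(mean=m, variance=tiny, corr_len=1.0)
            for m in (400.0, 270.0, 490.0)
        ),
        bias_amplitude=0.0,
        class_adc_contrast=(0.0, 0.0, 0.0),
        gain_sd_t2=0.0,
        gain_sd_adc=0.0,
        blend_sigma=0.0,
        psf_sigma=0.0,
        noise_sd=0.0,
    )
    base.update(overrides)
    return small_phantom_spec(**base)


@pytest.fixture(scope="session")
def small_pair():
    pair, truth = generate_phantom(small_phantom_spec(), 7, is_cs=True)
    return pair, truth


@pytest.fixture(scope="session")
def tiny_clinical_spec():
    return ClinicalSpec(n_cs=8, n_noncs=5)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
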