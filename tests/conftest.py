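"""Shared fixtures.

The default-configuration double-helix PSF stack is expensive enough to
share per session; solver unit tests use a tiny random stack so the
oracles stay fast and independent of the optics.
"""

import numpy as np
import pytest

from rotoloc.config import OpticalConfig
from rotoloc.optics import PSFStack, build_psf_stack, double_helix_mask, flat_mask


@pytest.fixture(scope="session")
def config() -> OpticalConfig:
    return OpticalConfig()


@pytest.fixture(scope="session")
def dh_mask(config):
    return double_helix_mask(config)


@pytest.fixture(scope="session")
def dh_stack(config, dh_mask) -> PSFStack:
    return build_psf_stack(config, dh_mask)


@pytest.fixture(scope="session")
def flat_stack(config) -> PSFStack:
    return build_psf_stack(config, flat_mask(config))


@pytest.fixture()
def tiny_stack() -> PSFStack:
    """Small random nonnegative stack for solver-level oracles."""
    rng = np.random.default_rng(7)
    values = rng.random((3, 5, 5))
    return PSFStack(
        values=values,
        z_planes_nm=np.array([-50.0, 0.0, 50.0]),
        lateral_step_nm=100.0,
        axial_step_nm=50.0,
    )
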