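"""Shared fixtures: small synthetic images with known truth."""

import numpy as np
import pytest

from crumbscope import CrumbSimParams, generate_crumb_micrograph


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def small_params():
    """Compact crumb simulation (fast to generate, fast to segment)."""
    return CrumbSimParams(
        image_size_px=(256, 256),
        target_porosity_pct=65.0,
        target_poia_pct=15.0,
        crust_band_px=16,
        noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def small_crumb(small_params):
    """One noise-free synthetic crumb micrograph with its truth."""
    return generate_crumb_micrograph(small_params, seed=1)
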