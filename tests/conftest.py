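"""Shared fixtures: desk-scale phantoms and tumor banks, generated once."""

import numpy as np
import pytest

from murilung.phantom import generate_thorax, generate_tumor_bank


@pytest.fixture(scope="session")
def small_phantom():
    """Noise-free 300 um thorax phantom for projection-domain tests."""
    return generate_thorax(
        np.random.default_rng(7), spacing_um=300.0, shape=(64, 72, 72), noise_hu=0.0
    )


@pytest.fixture(scope="session")
def noisy_phantom():
    """300 um thorax phantom with realistic noise for segmentation/training."""
    return generate_thorax(
        np.random.default_rng(5), spacing_um=300.0, shape=(100, 80, 80), noise_hu=15.0
    )


@pytest.fixture(scope="session")
def small_bank():
    """Mid-size tumor templates at the small-phantom spacing."""
    return generate_tumor_bank(
        np.random.default_rng(13), n_templates=3, size_range_mm3=(6.0, 20.0),
        spacing_um=300.0, mean_hu=30.0, std_hu=40.0,
    )


@pytest.fixture(scope="session")
def default_phantom():
    """The package-default phantom (150 um, full thorax)."""
    return generate_thorax(np.random.default_rng(0))
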