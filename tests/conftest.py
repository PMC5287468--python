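"""Shared fixtures: canonical pore patches and small scenes.

Everything is generated at test time; session scope keeps the expensive
renders to one evaluation each.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from poremark.synthgen import (
    LARGE_PORE,
    MEDIUM_PORE,
    PoreClassMix,
    SheetScene,
    noise_sigma_for_snr,
    rectangle_mask,
    render_pore_patch,
    render_sheet,
)

PIXEL = 0.69


@pytest.fixture(scope="session")
def large_patch_noiseless():
    """Paper-default large pore, 0.69 nm/px, no noise, no tilt."""
    return render_pore_patch(LARGE_PORE, noise_sigma=0.0)


@pytest.fixture(scope="session")
def large_patch_snr3():
    """Paper-default large pore at SNR 3 (|contrast_outer|/sigma = 3)."""
    sigma = noise_sigma_for_snr(LARGE_PORE, 3.0)
    return render_pore_patch(LARGE_PORE, noise_sigma=sigma, seed=42)


@pytest.fixture(scope="session")
def circular_patch_noiseless():
    """Large pore with zero subunit modulation: circularly symmetric."""
    model = dataclasses.replace(LARGE_PORE, subunit_amplitude=0.0)
    return render_pore_patch(model, noise_sigma=0.0)


@pytest.fixture(scope="session")
def medium_patch_noiseless():
    return render_pore_patch(MEDIUM_PORE, noise_sigma=0.0)


@pytest.fixture(scope="session")
def small_sheet():
    """1 um x 1 um sheet at the cryo-EM fraction density, SNR 5."""
    sigma = noise_sigma_for_snr(LARGE_PORE, 5.0)
    scene = SheetScene(
        mask=rectangle_mask(1000.0, 1000.0, PIXEL),
        density=200.0,
        pore_mix=PoreClassMix.single(LARGE_PORE),
        noise_sigma=sigma,
        seed=3,
    )
    img, truth = render_sheet(scene)
    return scene, img, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
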