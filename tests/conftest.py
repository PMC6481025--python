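"""Shared fixtures: synthetic vessel images with known ground truth."""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from ocutort import (
    CurveParams,
    RasterParams,
    SeedTriplet,
    gen_centerline,
    place_centerline,
    rasterize_vessel,
)


@pytest.fixture(scope="session")
def sinusoid_scene():
    """A noiseless moderate-tortuosity vessel image with its ground truth.

    Returns (image, placed_centerline, seeds): sinusoid amplitude 10 px,
    wavelength 100 px, span 400 px on the full 1536 x 1024 frame, with
    seeds on the true centerline at 0 / 50 / 100 % of the span.
    """
    params = CurveParams(
        family="sinusoid", span_px=400, amplitude_px=10, wavelength_px=100,
        sample_spacing_px=2,
    )
    rp = RasterParams(noise_sd=0)
    placed = place_centerline(gen_centerline(params), rp)
    image = rasterize_vessel(placed, rp)
    seeds = SeedTriplet(placed[[0, len(placed) // 2, -1]])
    return image, placed, seeds


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
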