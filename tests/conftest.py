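"""Shared fixtures: geometry and clean, well-separated simulations."""

import numpy as np
import pytest
from hypothesis import settings

from mmiflow import (DetectorConfig, FlowGeometry, SimulationParams,
                     TransitRecord)

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture
def geom() -> FlowGeometry:
    """The reference channel: 5 x 12 µm cross-section, 75 µm MMI width."""
    return FlowGeometry(channel_cross_section=60.0, mmi_width=75.0)


def make_params(geom: FlowGeometry, **overrides) -> SimulationParams:
    """Bright, noise-friendly defaults for detector-level tests.

    The 3 µm spot FWHM keeps adjacent Gaussian peaks well separated at
    the default W/N spacing, so every transit shows n_spots resolved
    peaks above the end threshold.
    """
    kw = dict(concentration=3.4e6, velocity_mean=7500.0, geometry=geom,
              n_spots=7, spot_fwhm=3.0, peak_photon_rate=5e5,
              background_rate=0.0, duration=12.0, seed=0)
    kw.update(overrides)
    return SimulationParams(**kw)


@pytest.fixture
def clean_params(geom) -> SimulationParams:
    return make_params(geom)


@pytest.fixture
def clean_transits(clean_params) -> list[TransitRecord]:
    """20 deterministic, well-separated transits (0.5 s apart)."""
    return [TransitRecord(entry_time=0.25 + 0.5 * k, velocity=7500.0)
            for k in range(20)]


@pytest.fixture
def detector_config() -> DetectorConfig:
    return DetectorConfig(bin_width=100e-6, start_threshold=10.0,
                          end_threshold=5.0, wait_time=1e-3)
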