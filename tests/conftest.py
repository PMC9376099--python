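"""Shared fixtures: small geometries and synthetic ensembles."""

import numpy as np
import pytest

from wavepipe.containers import GridGeometry
from wavepipe.synth import WaveSpec, generate_traveling_wave


@pytest.fixture(scope="session")
def geometry() -> GridGeometry:
    """Standard 11 x 6 ECoG grid, 0.5 mm pitch."""
    return GridGeometry.rectangular()


@pytest.fixture(scope="session")
def slow_wave_ensemble(geometry):
    """Small slow-band (4.5 Hz, 12.5 mm) traveling-wave ensemble, SNR 10 dB."""
    wave = WaveSpec(direction=(0.0, 1.0), wavelength_mm=12.5, freq_hz=4.5,
                    onset=0.0, duration=0.9)
    return generate_traveling_wave(geometry, wave, n_trials=10, snr_db=10.0,
                                   seed=101)


@pytest.fixture(scope="session")
def fast_wave_ensemble(geometry):
    """Small fast-band (40 Hz, 12.7 mm) traveling-wave ensemble, SNR 10 dB."""
    wave = WaveSpec(direction=(0.0, 1.0), wavelength_mm=12.7, freq_hz=40.0,
                    onset=0.0, duration=0.35)
    return generate_traveling_wave(geometry, wave, n_trials=10, snr_db=10.0,
                                   seed=102)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
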