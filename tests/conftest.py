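import numpy as np
import pytest

import islandcardio as ic
from islandcardio import synth


@pytest.fixture(scope="session")
def small_layout():
    return ic.IslandLayout(shapes=[ic.Square(1, 100, (40, 40))],
                           pixel_size_um=5.0, field_um=(200.0, 200.0))


@pytest.fixture(scope="session")
def voltage_spec():
    return synth.WaveformSpec(kind="voltage", period_s=1.0, amplitude=0.4,
                              apd50_s=0.3, rise_time_s=0.05, f0=100.0)


@pytest.fixture(scope="session")
def small_movie(small_layout, voltage_spec):
    """One 100 um island, 200 Hz, 10 s, default nuisance levels."""
    spec = ic.MovieSpec(layout=small_layout, waveform=voltage_spec,
                        frame_rate_hz=200.0, duration_s=10.0,
                        background_level=200.0, bleach_tau_s=100.0,
                        noise_sd=2.0, seed=11)
    movie, truth = ic.render_movie(spec)
    return movie, truth


@pytest.fixture(scope="session")
def clean_movie(small_layout, voltage_spec):
    """Noiseless, bleach-free single-island movie with fixed phase."""
    spec = ic.MovieSpec(layout=small_layout, waveform=voltage_spec,
                        frame_rate_hz=200.0, duration_s=10.0,
                        background_level=200.0, bleach_tau_s=0.0,
                        noise_sd=0.0, period_jitter_cv=0.0,
                        random_phase=False, seed=1)
    movie, truth = ic.render_movie(spec)
    return movie, truth
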