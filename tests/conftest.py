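import numpy as np
import pytest

from radarbreath.radar_model import RadarConfig
from radarbreath.synthetic_scene import NoiseSpec, make_user, simulate_session


@pytest.fixture(scope="session")
def cfg():
    return RadarConfig()


@pytest.fixture(scope="session")
def small_cfg():
    """Reduced geometry for fast I/O-heavy tests; physics unchanged."""
    return RadarConfig(n_chirps=2, n_samples=64)


@pytest.fixture(scope="session")
def idle_record(cfg):
    """A clean breathing session: no motion, no noise."""
    profile = make_user(7, overrides={"motion_rate": 0.0})
    return simulate_session(
        profile, cfg, seed=7,
        noise=NoiseSpec(adc_noise_std=0.0, belt_noise_std=0.0),
    )


@pytest.fixture(scope="session")
def idle_profile():
    return make_user(7, overrides={"motion_rate": 0.0})


@pytest.fixture(scope="session")
def noisy_record(cfg):
    """A realistic session with default noise and motion."""
    return simulate_session(make_user(11), cfg, seed=11)


def spectral_peak_hz(x, fs, band=(0.05, 0.6), pad=8):
    """Zero-padded periodogram argmax inside a band (shared test oracle)."""
    x = np.asarray(x, dtype=float)
    n = len(x) * pad
    spec = np.abs(np.fft.rfft(x - x.mean(), n=n))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    m = (freqs >= band[0]) & (freqs <= band[1])
    return float(freqs[m][np.argmax(spec[m])])
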