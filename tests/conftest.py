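import numpy as np
import pytest

from hearsim.audiogram import REQUIRED_FREQUENCIES, Audiogram
from hearsim.buffer import AudioBuffer
from hearsim.calibration import default_calibration
from hearsim.signals import generate_fixture


@pytest.fixture(scope="session")
def calib():
    return default_calibration()


@pytest.fixture(scope="session")
def speech():
    """Conversational speech-shaped fixture at the calibrated level."""
    return generate_fixture("speech_shaped", duration=6.0, rate=44100, seed=11)


@pytest.fixture(scope="session")
def speech_short():
    return generate_fixture("speech_shaped", duration=2.0, rate=44100, seed=11)


def make_gated_tone(freq_hz, rms, rate=44100, duration=0.5, ramp_s=0.02):
    """Sine probe with raised-cosine gating to avoid onset/offset splatter."""
    n = int(duration * rate)
    x = np.sqrt(2.0) * rms * np.sin(2 * np.pi * freq_hz * np.arange(n) / rate)
    nr = int(ramp_s * rate)
    env = np.ones(n)
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
    env[:nr] = ramp
    env[-nr:] = ramp[::-1]
    return AudioBuffer(x * env, rate)


def random_audiogram(rng):
    """Clinically plausible random audiogram (package generator)."""
    from hearsim.audiogram import random_audiogram as _gen

    return _gen(rng)


def band_energy_db(x, rate, f_lo, f_hi):
    """Energy (dB) of a mono signal in [f_lo, f_hi) via Hann-windowed rFFT
    (windowing keeps the leakage floor ~100 dB down so deep attenuations
    are measurable) — independent of the package's analysis code."""
    x = np.asarray(x, dtype=float)
    spec = np.fft.rfft(x * np.hanning(len(x)))
    freqs = np.fft.rfftfreq(len(x), d=1.0 / rate)
    sel = (freqs >= f_lo) & (freqs < f_hi)
    p = np.sum(np.abs(spec[sel]) ** 2)
    return 10.0 * np.log10(max(p, 1e-300))
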