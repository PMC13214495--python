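"""Seed-reproducible test and demonstration signals.

Recorded phonetically balanced speech cannot be redistributed, so the
simulator ships formula-defined stand-ins:

* ``speech_shaped`` — Gaussian noise spectrally shaped like running
  speech (flat 100–500 Hz, −9 dB/octave above 500 Hz) and amplitude
  modulated at 4 Hz with depth 0.6 to mimic the syllabic envelope.
* ``babble`` — the sum of 8 independently seeded speech-shaped streams
  with random modulation phases (multi-talker background noise).
* ``tone:<freqHz>`` — a pure sine probe.
* ``music_tones`` — an arpeggiated harmonic tone sequence spanning
  262–3520 Hz, a schematic stand-in for instrumental music.
* ``white`` — Gaussian white noise.

All fixtures are scaled to an exact target RMS (default 0.05, the level
the default calibration maps to conversational speech) and are
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np

from .buffer import AudioBuffer
from .calibration import DEFAULT_FIXTURE_RMS

#: Speech-shaping corner frequencies and slope.
_SPEECH_FLAT_LO_HZ = 100.0
_SPEECH_CORNER_HZ = 500.0
_SPEECH_SLOPE_DB_PER_OCT = -9.0
_AM_RATE_HZ = 4.0
_AM_DEPTH = 0.6

#: Arpeggio fundamentals (Hz), C-major triad notes from C4 up to A7.
_MUSIC_NOTES = (
    261.63, 329.63, 392.00, 523.25, 659.26, 783.99,
    1046.50, 1318.51, 1567.98, 2093.00, 2637.02, 3135.96, 3520.00,
)

FIXTURE_NAMES = ("speech_shaped", "babble", "music_tones", "white", "tone:<freqHz>")


def _speech_shaping_db(freqs: np.ndarray) -> np.ndarray:
    """Spectral magnitude shaping in dB: flat 100-500 Hz, -9 dB/oct above,
    +12 dB/oct rolloff below 100 Hz to suppress rumble."""
    f = np.maximum(freqs, 1e-6)
    g = np.zeros_like(f)
    above = f > _SPEECH_CORNER_HZ
    g[above] = _SPEECH_SLOPE_DB_PER_OCT * np.log2(f[above] / _SPEECH_CORNER_HZ)
    below = f < _SPEECH_FLAT_LO_HZ
    g[below] = -12.0 * np.log2(_SPEECH_FLAT_LO_HZ / f[below])
    return g


def _scale_to_rms(x: np.ndarray, rms: float) -> np.ndarray:
    cur = np.sqrt(np.mean(np.square(x)))
    return x * (rms / cur)


def _speech_shaped(n: int, rate: int, rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal(n)
    spec = np.fft.rfft(noise)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    spec *= 10.0 ** (_speech_shaping_db(freqs) / 20.0)
    shaped = np.fft.irfft(spec, n=n)
    t = np.arange(n) / rate
    phase = rng.uniform(0.0, 2.0 * np.pi)
    am = 1.0 + _AM_DEPTH * np.sin(2.0 * np.pi * _AM_RATE_HZ * t + phase)
    return shaped * am


def _music_tones(n: int, rate: int) -> np.ndarray:
    note_len = int(round(0.2 * rate))
    t = np.arange(note_len) / rate
    env = np.sin(np.pi * np.arange(note_len) / note_len) ** 2  # Hann-shaped note
    out = np.zeros(n)
    pos = 0
    k = 0
    while pos < n:
        f0 = _MUSIC_NOTES[k % len(_MUSIC_NOTES)]
        note = np.sin(2 * np.pi * f0 * t)
        for mult, level_db in ((2, -12.0), (3, -18.0)):
            if f0 * mult < rate / 2:
                note = note + 10 ** (level_db / 20.0) * np.sin(2 * np.pi * f0 * mult * t)
        seg = min(note_len, n - pos)
        out[pos : pos + seg] = (note * env)[:seg]
        pos += note_len
        k += 1
    return out


def generate_fixture(
    name: str,
    duration: float = 5.0,
    rate: int = 44100,
    seed: int = 0,
    rms: float = DEFAULT_FIXTURE_RMS,
) -> AudioBuffer:
    """Synthesize a named fixture at an exact target RMS.

    ``name`` is one of ``speech_shaped``, ``babble``, ``music_tones``,
    ``white``, or ``tone:<freqHz>`` (e.g. ``tone:1000``).  Identical
    arguments always produce bit-identical buffers.
    """
    n = int(round(duration * rate))
    if n < 1:
        raise ValueError("duration too short for the sample rate")
    rng = np.random.default_rng(seed)
    if name == "white":
        x = rng.standard_normal(n)
    elif name == "speech_shaped":
        x = _speech_shaped(n, rate, rng)
    elif name == "babble":
        streams = np.random.SeedSequence(seed).spawn(8)
        x = np.zeros(n)
        for child in streams:
            x += _speech_shaped(n, rate, np.random.default_rng(child))
    elif name == "music_tones":
        x = _music_tones(n, rate)
    elif name.startswith("tone:"):
        try:
            f0 = float(name.split(":", 1)[1])
        except ValueError:
            raise KeyError(f"bad tone fixture {name!r}; use e.g. 'tone:1000'") from None
        if not 0 < f0 < rate / 2:
            raise ValueError(f"tone frequency {f0:g} Hz outside (0, Nyquist)")
        x = np.sin(2 * np.pi * f0 * np.arange(n) / rate)
    else:
        raise KeyError(f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}")
    return AudioBuffer(_scale_to_rms(x, rms), rate)
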