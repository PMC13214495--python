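"""Listening environments: background noise at a set SNR and talker distance.

Two acoustic transforms precede the hearing profiles:

* noise mixing — a background noise is scaled so the speech-to-noise
  RMS ratio equals the requested SNR (defined at the reference
  distance), then added; the speech component itself is untouched;
* distance — speech level falls with the inverse square law,
  -20*log10(d/d_ref) dB relative to the reference distance (1 m by
  default).  Noise is treated as ambient and is NOT distance-scaled,
  so moving the talker away degrades the effective SNR.

No reverberation or air absorption is modeled — intensity only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np

from .buffer import AudioBuffer
from .signals import generate_fixture

FT_PER_M = 0.3048  # exact

ENVIRONMENT_KINDS = ("quiet", "noise", "distance", "music")
PROFILE_MODES = ("normal", "unaided", "aided")


@dataclass(frozen=True)
class Scenario:
    """Environment descriptor driving the render pipeline.

    ``kind`` selects the transform; ``snr_db`` is required for noise
    scenarios and ``distance`` for distance scenarios (a noise scenario
    may also carry a distance, degrading the effective SNR).
    """

    kind: str = "quiet"
    mode: str = "normal"
    snr_db: float | None = None
    distance: float | None = None
    distance_unit: str = "m"
    reference_distance_m: float = 1.0
    noise: str = "fixture:babble"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ENVIRONMENT_KINDS:
            raise ValueError(f"kind must be one of {ENVIRONMENT_KINDS}, got {self.kind!r}")
        if self.mode not in PROFILE_MODES:
            raise ValueError(f"mode must be one of {PROFILE_MODES}, got {self.mode!r}")
        if self.kind == "noise" and self.snr_db is None:
            raise ValueError("noise scenarios require snr_db")
        if self.kind == "distance" and self.distance is None:
            raise ValueError("distance scenarios require a distance")
        if self.snr_db is not None and not math.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")
        if self.distance is not None and self.distance <= 0:
            raise ValueError("distance must be positive")
        if self.reference_distance_m <= 0:
            raise ValueError("reference distance must be positive")
        if self.distance_unit not in ("m", "ft"):
            raise ValueError(f"distance unit must be 'm' or 'ft', got {self.distance_unit!r}")

    @property
    def distance_m(self) -> float | None:
        if self.distance is None:
            return None
        return self.distance * FT_PER_M if self.distance_unit == "ft" else self.distance


def to_meters(d: float, unit: str = "m") -> float:
    if unit == "m":
        return d
    if unit == "ft":
        return d * FT_PER_M
    raise ValueError(f"unknown distance unit {unit!r}")


def distance_attenuation_db(d: float, d_ref: float = 1.0, unit: str = "m",
                            ref_unit: str = "m") -> float:
    """Level change (dB) moving a point source from ``d_ref`` to ``d``.

    Inverse square law: intensity falls as 1/d^2, so the level change is
    -20*log10(d/d_ref) — negative (a loss) beyond the reference
    distance, -6.02 dB per doubling.
    """
    if d <= 0 or d_ref <= 0:
        raise ValueError("distances must be positive")
    return -20.0 * math.log10(to_meters(d, unit) / to_meters(d_ref, ref_unit))


def mix_at_snr(speech: AudioBuffer, noise: AudioBuffer, snr_db: float) -> AudioBuffer:
    """Overlay noise on speech at an exact broadband SNR.

    The noise is trimmed to the speech length (never looped) and scaled
    so that ``20*log10(RMS_speech / RMS_noise) == snr_db`` over the
    overlapping segment; the speech component is added unscaled.
    """
    if speech.rate != noise.rate:
        raise ValueError(f"sample-rate mismatch: speech {speech.rate}, noise {noise.rate}")
    if noise.n_samples < speech.n_samples:
        raise ValueError(
            f"noise ({noise.n_samples} samples) shorter than speech ({speech.n_samples})"
        )
    s = speech.to_mono() if not speech.is_mono else speech
    n = noise.to_mono() if not noise.is_mono else noise
    n_trim = n.samples[: s.n_samples]
    rms_n = float(np.sqrt(np.mean(np.square(n_trim))))
    if rms_n == 0.0:
        raise ValueError("noise is silent (RMS = 0); cannot set an SNR")
    scale = s.rms() / rms_n * 10.0 ** (-snr_db / 20.0)
    return AudioBuffer(s.samples + scale * n_trim, s.rate)


NoiseProvider = Callable[[str, int, int, int], AudioBuffer]


def _default_noise_provider(source: str, n_samples: int, rate: int, seed: int) -> AudioBuffer:
    """Resolve ``fixture:<name>`` via the signal generator, else a WAV path."""
    if source.startswith("fixture:"):
        name = source.split(":", 1)[1]
        return generate_fixture(name, duration=n_samples / rate, rate=rate, seed=seed)
    from .audio_io import read_wav

    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(f"noise source {source!r} not found")
    return read_wav(path).to_mono()


def apply_environment(
    speech: AudioBuffer,
    scenario: Scenario,
    noise_provider: NoiseProvider = _default_noise_provider,
) -> AudioBuffer:
    """Apply the scenario's acoustic transform to the (mono) sound field.

    quiet/music: unchanged.  distance: speech scaled by the inverse
    square law.  noise: SNR set against the speech level at the
    reference distance, then distance scaling of the speech only, so
    the measured SNR is ``snr_db + attenuation`` when both are given.
    """
    x = speech.to_mono() if not speech.is_mono else speech
    if scenario.kind in ("quiet", "music"):
        return x
    att_db = 0.0
    if scenario.distance_m is not None:
        att_db = distance_attenuation_db(scenario.distance_m, scenario.reference_distance_m)
    if scenario.kind == "distance":
        return x.scaled(10.0 ** (att_db / 20.0))
    # noise scenario: scale the noise against the reference-distance speech,
    # then attenuate the speech component alone.
    noise = noise_provider(scenario.noise, x.n_samples, x.rate, scenario.seed)
    if noise.rate != x.rate:
        raise ValueError("noise sample rate does not match speech")
    if noise.n_samples < x.n_samples:
        raise ValueError("noise source shorter than speech")
    n_trim = noise.to_mono().samples[: x.n_samples]
    rms_n = float(np.sqrt(np.mean(np.square(n_trim))))
    if rms_n == 0.0:
        raise ValueError("noise is silent (RMS = 0)")
    scale = x.rms() / rms_n * 10.0 ** (-scenario.snr_db / 20.0)
    return AudioBuffer(x.samples * 10.0 ** (att_db / 20.0) + scale * n_trim, x.rate)
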