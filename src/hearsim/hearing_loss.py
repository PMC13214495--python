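"""Unaided hearing-loss simulation.

The loss model is pure intensity attenuation: at every frequency the
signal is reduced by exactly the threshold elevation, gain_dB(f) =
-HL(f), applied per ear through the zero-phase STFT filterbank.  No
loudness recruitment, spectral smearing, or temporal distortion is
modeled — the simulation reproduces audibility decrements across
frequency bands only.
"""

from __future__ import annotations

import logging

import numpy as np

from .audiogram import Audiogram, BandGains
from .buffer import AudioBuffer, stack_stereo
from .filterbank import FilterbankSpec, apply_band_gains

log = logging.getLogger(__name__)


def loss_band_gains(ag: Audiogram, ear: str) -> BandGains:
    """Attenuation curve for one ear: gain = -threshold at each audiogram point.

    Interpolating these band gains in dB vs log-frequency reproduces the
    audiogram's own interpolation, so per-band output attenuation equals
    the interpolated threshold.
    """
    freqs = ag.frequencies(ear)
    thr = ag.thresholds(ear)
    return BandGains(centers=tuple(freqs), gains=tuple(-thr))


def attenuate_ear(
    x: AudioBuffer, ag: Audiogram, ear: str, spec: FilterbankSpec | None = None
) -> AudioBuffer:
    """Apply one ear's threshold-elevation attenuation to a mono path."""
    return apply_band_gains(x, loss_band_gains(ag, ear), spec)


def clip_check(x: AudioBuffer, context: str = "output") -> tuple[AudioBuffer, int]:
    """Hard-clip samples beyond full scale; log a warning with the count."""
    n_clip = int(np.sum(np.abs(x.samples) > 1.0))
    if n_clip:
        log.warning("%s: hard-clipped %d samples exceeding full scale", context, n_clip)
        return AudioBuffer(np.clip(x.samples, -1.0, 1.0), x.rate), n_clip
    return x, 0


def simulate_unaided(x: AudioBuffer, ag: Audiogram) -> AudioBuffer:
    """Render the unaided hearing-loss profile (stereo output).

    A mono input is duplicated to both ear paths; a stereo input's
    channels are treated as the left/right paths directly.  Each ear is
    attenuated by its own interpolated thresholds independently.
    """
    stereo = x.to_stereo()
    left = attenuate_ear(stereo.channel(0), ag, "left")
    right = attenuate_ear(stereo.channel(1), ag, "right")
    return stack_stereo(left, right)
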