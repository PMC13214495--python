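"""Aided profile: prescriptive gain and multi-channel WDRC.

The hearing-aid stage prescribes per-channel compression parameters
from the audiogram and applies wide dynamic range compression (WDRC)
before the impaired-ear attenuation filter, so aided sound is heard
*through* the hearing loss.

Prescription rules live in a registry keyed by name.  The default,
``"dsl_like_halfgain"``, is a self-contained half-gain rule with a
loss-dependent compression ratio: G65 = 0.5*HL (clamped to [0, 50] dB),
CR = 1 + HL/100 (clamped to [1, 3]), kneepoint 40 dB SPL, output
ceiling 105 dB SPL.  It preserves the qualitative fitting contract —
audibility improves where there is loss, normal hearing is not
restored — while leaving room for a table-driven rule (e.g. a faithful
DSL v5.0 port) to be registered later.

Compression operates in acoustic units: the per-channel envelope is
converted to dB SPL through the calibration map so the kneepoint and
ceiling have physical meaning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .audiogram import Audiogram, interpolate_to_bands
from .buffer import AudioBuffer, stack_stereo
from .calibration import CalibrationMap
from .filterbank import split_bands
from .hearing_loss import attenuate_ear

try:  # envelope follower is a tight per-sample recursion; JIT when possible
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

#: Octave-spaced internal channel edges (Hz); outer edges are 0 and Nyquist.
DEFAULT_CHANNEL_EDGES = (250.0, 500.0, 1000.0, 2000.0, 4000.0)
DEFAULT_KNEE_SPL = 40.0
DEFAULT_CEILING_SPL = 105.0
DEFAULT_ATTACK_MS = 5.0
DEFAULT_RELEASE_MS = 100.0


@dataclass(frozen=True)
class CompressorParams:
    """Per-channel WDRC configuration.

    ``edges`` are the contiguous channel boundaries from 0 to Nyquist
    (len = n_channels + 1).  Per channel: ``knee_spl`` is the lower
    kneepoint (dB SPL input) above which compression engages,
    ``ratio`` the compression ratio (>= 1), ``gain65`` the gain at a
    65 dB SPL input, and ``ceiling_spl`` the hard output limit.
    Attack/release times are global, in milliseconds.
    """

    edges: tuple
    knee_spl: tuple
    ratio: tuple
    gain65: tuple
    ceiling_spl: tuple
    attack_ms: float = DEFAULT_ATTACK_MS
    release_ms: float = DEFAULT_RELEASE_MS

    def __post_init__(self) -> None:
        n = len(self.edges) - 1
        if n < 1:
            raise ValueError("need at least one channel")
        for name in ("knee_spl", "ratio", "gain65", "ceiling_spl"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have one value per channel ({n})")
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("channel edges must be strictly ascending")
        if any(r < 1.0 for r in self.ratio):
            raise ValueError("compression ratios must be >= 1")
        if any(not 20.0 <= k <= 60.0 for k in self.knee_spl):
            raise ValueError("kneepoints must lie in [20, 60] dB SPL")
        if any(c < k for c, k in zip(self.ceiling_spl, self.knee_spl)):
            raise ValueError("ceiling must be >= kneepoint")
        if not 0 < self.attack_ms < self.release_ms:
            raise ValueError("require 0 < attack < release")

    @property
    def n_channels(self) -> int:
        return len(self.edges) - 1

    def channel_centers(self) -> np.ndarray:
        """Representative (geometric-mean) frequency per channel.

        The first channel's lower edge is taken as 125 Hz for the mean so
        the center stays inside the audiometric interpolation range.
        """
        lo = np.asarray(self.edges[:-1], dtype=float)
        hi = np.asarray(self.edges[1:], dtype=float)
        lo[0] = max(lo[0], 125.0)
        return np.sqrt(lo * hi)


def _dsl_like_halfgain(hl: np.ndarray) -> dict:
    g65 = np.clip(0.5 * hl, 0.0, 50.0)
    cr = np.clip(1.0 + hl / 100.0, 1.0, 3.0)
    return {"gain65": g65, "ratio": cr}


PRESCRIPTION_RULES: dict[str, Callable[[np.ndarray], dict]] = {
    "dsl_like_halfgain": _dsl_like_halfgain,
}


def prescribe(
    ag: Audiogram,
    ear: str,
    rule: str = "dsl_like_halfgain",
    rate: int = 44100,
) -> CompressorParams:
    """Prescribe WDRC parameters for one ear from the audiogram.

    Six channels with octave-spaced edges from 250 Hz; the rule maps the
    threshold interpolated at each channel center to gain and ratio.
    Zero loss prescribes a transparent channel (G65 = 0, CR = 1).
    """
    if rule not in PRESCRIPTION_RULES:
        raise KeyError(
            f"unknown prescription rule {rule!r}; available: {sorted(PRESCRIPTION_RULES)}"
        )
    edges = (0.0, *DEFAULT_CHANNEL_EDGES, rate / 2.0)
    n = len(edges) - 1
    params = CompressorParams(
        edges=edges,
        knee_spl=(DEFAULT_KNEE_SPL,) * n,
        ratio=(1.0,) * n,
        gain65=(0.0,) * n,
        ceiling_spl=(DEFAULT_CEILING_SPL,) * n,
    )
    hl = interpolate_to_bands(ag, ear, params.channel_centers())
    fit = PRESCRIPTION_RULES[rule](hl)
    return CompressorParams(
        edges=edges,
        knee_spl=(DEFAULT_KNEE_SPL,) * n,
        ratio=tuple(float(r) for r in fit["ratio"]),
        gain65=tuple(float(g) for g in fit["gain65"]),
        ceiling_spl=(DEFAULT_CEILING_SPL,) * n,
    )


def static_io_curve(p: CompressorParams, channel: int, input_spl: float) -> float:
    """Steady-state input/output level map (dB SPL) for one channel.

    Linear (slope 1) below the kneepoint, slope 1/CR above it; the two
    segments meet continuously at the knee and the compressed segment
    passes through (65, 65 + G65).  A hard ceiling caps the output.
    """
    knee = p.knee_spl[channel]
    cr = p.ratio[channel]
    g65 = p.gain65[channel]
    out65 = 65.0 + g65
    if input_spl >= knee:
        out = out65 + (input_spl - 65.0) / cr
    else:
        out = out65 + (knee - 65.0) / cr + (input_spl - knee)
    return min(out, p.ceiling_spl[channel])


def _static_gain_db(level_spl: np.ndarray, knee: float, cr: float, g65: float,
                    ceiling: float) -> np.ndarray:
    out65 = 65.0 + g65
    out = np.where(
        level_spl >= knee,
        out65 + (level_spl - 65.0) / cr,
        out65 + (knee - 65.0) / cr + (level_spl - knee),
    )
    return np.minimum(out, ceiling) - level_spl


def _attack_release_py(power: np.ndarray, ca: float, cr: float) -> np.ndarray:
    env = np.empty_like(power)
    e = power[0]
    for i in range(power.size):
        x = power[i]
        c = ca if x > e else cr
        e = c * e + (1.0 - c) * x
        env[i] = e
    return env


if _HAVE_NUMBA:
    _attack_release = njit(cache=True)(_attack_release_py)
else:  # pragma: no cover
    _attack_release = _attack_release_py


#: Symmetric carrier-ripple smoother time constant (s); two one-pole
#: stages with unity DC gain, so steady-state levels are unaffected.
PRE_SMOOTH_TAU_S = 0.005


def envelope_spl(
    band: np.ndarray,
    rate: int,
    calib: CalibrationMap,
    attack_ms: float,
    release_ms: float,
) -> np.ndarray:
    """Attack/release-smoothed level trace (dB SPL) of one channel signal.

    The instantaneous power is first passed through two symmetric
    one-pole stages (5 ms) to strip the carrier ripple of tonal content,
    then through the asymmetric attack/release one-pole (fast when the
    input exceeds the envelope, slow when it falls below), and converted
    to SPL through the calibration map.  Both smoothers have unity DC
    gain, so for a steady tone the envelope converges to the exact mean
    square and steady-state levels match the RMS-based calibration.
    """
    from scipy.signal import lfilter

    a = float(np.exp(-1.0 / (rate * PRE_SMOOTH_TAU_S)))
    p = np.square(band)
    p = lfilter([1.0 - a], [1.0, -a], p)
    p = lfilter([1.0 - a], [1.0, -a], p)
    ca = float(np.exp(-1.0 / (rate * attack_ms * 1e-3)))
    cr = float(np.exp(-1.0 / (rate * release_ms * 1e-3)))
    env = _attack_release(np.maximum(p, 0.0), ca, cr)
    return calib.spl_from_power(env)


def compress(x: AudioBuffer, p: CompressorParams, calib: CalibrationMap) -> AudioBuffer:
    """Multi-channel WDRC of a mono signal.

    The signal is split into contiguous channels on the STFT filterbank
    grid (complementary linear-phase masks), each channel's envelope
    drives a time-varying gain following :func:`static_io_curve`, and
    the processed channels are summed.  Output length equals input
    length; the chain is deterministic.
    """
    if not x.is_mono:
        raise ValueError("compress expects a mono buffer (one ear path)")
    bands = split_bands(x, p.edges)
    y = np.zeros(x.n_samples)
    for ch, band in enumerate(bands):
        level = envelope_spl(band, x.rate, calib, p.attack_ms, p.release_ms)
        gain_db = _static_gain_db(
            level, p.knee_spl[ch], p.ratio[ch], p.gain65[ch], p.ceiling_spl[ch]
        )
        y += band * 10.0 ** (gain_db / 20.0)
    return AudioBuffer(y, x.rate)


def simulate_aided(
    x: AudioBuffer,
    ag: Audiogram,
    calib: CalibrationMap,
    rule: str = "dsl_like_halfgain",
) -> AudioBuffer:
    """Render the aided profile (stereo): per ear, WDRC then loss filter.

    The compressed (amplified) signal is passed through that ear's
    threshold-elevation attenuation — aided sound as heard through the
    impaired ear.  With the default half-gain rule the aided output is
    louder than unaided but quieter than normal hearing whenever there
    is loss.
    """
    stereo = x.to_stereo()
    ears = []
    for chan, earname in ((0, "left"), (1, "right")):
        params = prescribe(ag, earname, rule=rule, rate=stereo.rate)
        aided = compress(stereo.channel(chan), params, calib)
        ears.append(attenuate_ear(aided, ag, earname))
    return stack_stereo(*ears)
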