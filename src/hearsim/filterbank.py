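"""Zero-phase STFT filterbank used by the loss and hearing-aid stages.

Square-root Hann analysis and synthesis windows at 75% overlap satisfy
the constant-overlap-add condition exactly, so a unity-gain round trip
reconstructs the signal to machine precision.  Per-bin real gains give a
zero-phase frequency response (no frequency-dependent group delay); the
STFT's uniform latency is compensated by trimming the edge padding.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.signal import ShortTimeFFT, windows

from .audiogram import BandGains
from .buffer import AudioBuffer


@dataclass(frozen=True)
class FilterbankSpec:
    """STFT analysis grid: FFT size, hop, window, and band edges.

    The hop must divide the FFT size; the default sqrt-Hann window pair
    at hop = n_fft/4 is COLA-exact.  Band edges ascend from 0 to the
    Nyquist frequency and partition the spectrum into contiguous
    channels (used by the compressor's band split).
    """

    n_fft: int
    hop: int
    window: str = "sqrt_hann"
    band_edges: tuple = ()

    def __post_init__(self) -> None:
        if self.n_fft <= 0 or self.hop <= 0 or self.n_fft % self.hop != 0:
            raise ValueError(f"hop ({self.hop}) must divide n_fft ({self.n_fft})")
        if self.window != "sqrt_hann":
            raise ValueError(f"unsupported window {self.window!r}")
        edges = tuple(float(e) for e in self.band_edges)
        if edges and any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("band edges must be strictly ascending")
        object.__setattr__(self, "band_edges", edges)

    @staticmethod
    def for_rate(rate: int, band_edges: tuple = ()) -> "FilterbankSpec":
        """Default spec: 2048-point FFT above 22.05 kHz, else 1024; hop n/4."""
        n_fft = 2048 if rate > 22050 else 1024
        return FilterbankSpec(n_fft=n_fft, hop=n_fft // 4, band_edges=band_edges)


@lru_cache(maxsize=8)
def _stft(n_fft: int, hop: int, rate: int) -> ShortTimeFFT:
    win = np.sqrt(windows.hann(n_fft, sym=False))
    return ShortTimeFFT(win, hop=hop, fs=float(rate), fft_mode="onesided")


def bin_gains_db(gains: BandGains, rate: int, n_fft: int) -> np.ndarray:
    """Interpolate band gains (dB) onto the rFFT bin grid.

    dB-vs-log2(frequency) interpolation with flat extrapolation beyond
    the outermost band centers; the DC bin takes the lowest band's gain.
    """
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / rate)
    centers = np.asarray(gains.centers, dtype=float)
    if centers.max() > rate / 2:
        raise ValueError(
            f"gain center {centers.max():g} Hz exceeds Nyquist ({rate / 2:g} Hz)"
        )
    f = np.maximum(freqs, centers[0])  # DC folds onto the lowest band
    return np.interp(np.log2(f), np.log2(centers), np.asarray(gains.gains, dtype=float))


def apply_bin_gains(x: AudioBuffer, linear_gains: np.ndarray) -> AudioBuffer:
    """Scale each STFT bin of a mono signal by a real gain and resynthesize."""
    if not x.is_mono:
        raise ValueError("apply_bin_gains expects a mono buffer (one ear path)")
    spec = FilterbankSpec.for_rate(x.rate)
    st = _stft(spec.n_fft, spec.hop, x.rate)
    pad = spec.n_fft
    xp = np.pad(x.samples, pad)
    S = st.stft(xp)
    S *= np.asarray(linear_gains, dtype=float)[:, None]
    y = st.istft(S, k1=len(xp))[pad : pad + x.n_samples]
    return AudioBuffer(y, x.rate)


def apply_band_gains(
    x: AudioBuffer, gains: BandGains, spec: FilterbankSpec | None = None
) -> AudioBuffer:
    """Apply a per-band gain curve (dB) to a mono signal, zero-phase.

    Gains are interpolated from the band centers onto every FFT bin
    (dB vs log-frequency, flat beyond the ends) and applied as real
    multipliers in the STFT domain.  Output has the same length and
    sample rate as the input.
    """
    if not x.is_mono:
        raise ValueError("apply_band_gains expects a mono buffer (one ear path)")
    spec = spec or FilterbankSpec.for_rate(x.rate)
    g_db = bin_gains_db(gains, x.rate, spec.n_fft)
    st = _stft(spec.n_fft, spec.hop, x.rate)
    pad = spec.n_fft
    xp = np.pad(x.samples, pad)
    S = st.stft(xp)
    S *= (10.0 ** (g_db / 20.0))[:, None]
    y = st.istft(S, k1=len(xp))[pad : pad + x.n_samples]
    return AudioBuffer(y, x.rate)


@lru_cache(maxsize=16)
def _lowpass_bank(edges: tuple, rate: int) -> tuple:
    """Zero-phase FIR lowpass kernels at each internal band edge.

    Kaiser designs with ~70 dB stopband and a transition width of 25% of
    the edge frequency (capped at 400 Hz), so a channel's neighbors leak
    at most about -70 dB into it even under large prescribed gains.
    """
    from scipy.signal import firwin, kaiserord

    kernels = []
    for e in edges:
        width = min(0.25 * e, 400.0)
        numtaps, beta = kaiserord(70.0, width / (rate / 2.0))
        numtaps |= 1  # odd length -> integer group delay, exactly symmetric
        kernels.append(firwin(numtaps, e, window=("kaiser", beta), fs=rate))
    return tuple(kernels)


def split_bands(x: AudioBuffer, edges) -> list[np.ndarray]:
    """Split a mono signal into contiguous frequency channels.

    Each channel is the difference of two zero-phase FIR lowpass
    outputs at its edges (the lowest channel's lower edge is DC, the
    highest channel's upper edge Nyquist), so the channel signals
    telescope to exactly the input when summed — a perfectly
    complementary, linear-phase band split with delay compensated.
    """
    if not x.is_mono:
        raise ValueError("split_bands expects a mono buffer")
    edges = [float(e) for e in edges]
    internal = [e for e in edges if 0.0 < e < x.rate / 2.0]
    kernels = _lowpass_bank(tuple(internal), x.rate)

    from scipy.signal import fftconvolve

    lowpassed = []
    for h in kernels:
        delay = (len(h) - 1) // 2
        pad = np.pad(x.samples, delay)
        lowpassed.append(fftconvolve(pad, h, mode="same")[delay : delay + x.n_samples])
    cumulative = [np.zeros(x.n_samples), *lowpassed, x.samples]
    return [hi - lo for lo, hi in zip(cumulative[:-1], cumulative[1:])]
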