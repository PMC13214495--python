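"""Audio container used throughout the simulator.

All processing operates on :class:`AudioBuffer`: a float waveform in
dimensionless full-scale units (|x| <= 1 nominally), a sample rate, and
either one channel (a single ear path / sound field) or two channels
(independent left/right ear paths).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Sample rates the simulator accepts (Hz).
SUPPORTED_RATES = (16000, 22050, 32000, 44100, 48000)


@dataclass
class AudioBuffer:
    """A sampled waveform.

    Parameters
    ----------
    samples : ndarray
        Shape ``(n,)`` for mono or ``(n, 2)`` for stereo (columns are the
        left and right ear paths). Values are full-scale amplitude.
    rate : int
        Sample rate in Hz; one of :data:`SUPPORTED_RATES`.
    """

    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim == 2 and self.samples.shape[1] == 1:
            self.samples = self.samples[:, 0]
        if self.samples.ndim not in (1, 2):
            raise ValueError(f"samples must be 1-D or 2-D, got ndim={self.samples.ndim}")
        if self.samples.ndim == 2 and self.samples.shape[1] != 2:
            raise ValueError(
                f"stereo buffers must have exactly 2 channels, got {self.samples.shape[1]}"
            )
        if self.samples.shape[0] < 1:
            raise ValueError("buffer must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if int(self.rate) not in SUPPORTED_RATES:
            raise ValueError(f"sample rate {self.rate} not in supported set {SUPPORTED_RATES}")
        self.rate = int(self.rate)

    # -- shape helpers -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return 1 if self.samples.ndim == 1 else 2

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.rate

    @property
    def is_mono(self) -> bool:
        return self.n_channels == 1

    def channel(self, index: int) -> "AudioBuffer":
        """Extract one ear path as a mono buffer (0 = left, 1 = right)."""
        if self.is_mono:
            if index not in (0, 1):
                raise IndexError(index)
            return AudioBuffer(self.samples.copy(), self.rate)
        return AudioBuffer(self.samples[:, index].copy(), self.rate)

    def to_mono(self) -> "AudioBuffer":
        """Average channels into a single sound-field signal."""
        if self.is_mono:
            return AudioBuffer(self.samples.copy(), self.rate)
        return AudioBuffer(self.samples.mean(axis=1), self.rate)

    def to_stereo(self) -> "AudioBuffer":
        """Duplicate a mono sound field onto both ear paths."""
        if not self.is_mono:
            return AudioBuffer(self.samples.copy(), self.rate)
        return AudioBuffer(np.column_stack([self.samples, self.samples]), self.rate)

    # -- level helpers -------------------------------------------------

    def rms(self) -> float:
        """Root-mean-square amplitude over all samples (all channels pooled)."""
        return float(np.sqrt(np.mean(np.square(self.samples))))

    def channel_rms(self) -> np.ndarray:
        """Per-channel RMS; shape ``(n_channels,)``."""
        s = self.samples if self.samples.ndim == 2 else self.samples[:, None]
        return np.sqrt(np.mean(np.square(s), axis=0))

    def scaled(self, factor: float) -> "AudioBuffer":
        return AudioBuffer(self.samples * float(factor), self.rate)


def stack_stereo(left: AudioBuffer, right: AudioBuffer) -> AudioBuffer:
    """Combine two mono ear paths into one stereo buffer."""
    if not (left.is_mono and right.is_mono):
        raise ValueError("stack_stereo expects two mono buffers")
    if left.rate != right.rate or left.n_samples != right.n_samples:
        raise ValueError("ear paths must share rate and length")
    return AudioBuffer(np.column_stack([left.samples, right.samples]), left.rate)
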