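"""WAV read/write.

Float32 output is the default so the engine's tight passthrough
contracts survive a file round trip without quantization; PCM16 is
available for players that need it.  Integer WAVs are normalized to
full-scale float on read.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .buffer import AudioBuffer

_INT_SCALE = {np.dtype(np.int16): 2**15, np.dtype(np.int32): 2**31}


def read_wav(path: str | Path) -> AudioBuffer:
    """Read a WAV file into an :class:`AudioBuffer` (float, full scale)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"audio file not found: {path}")
    rate, data = wavfile.read(path)
    if data.dtype in _INT_SCALE:
        data = data.astype(np.float64) / _INT_SCALE[data.dtype]
    elif data.dtype == np.uint8:
        data = (data.astype(np.float64) - 128.0) / 128.0
    else:
        data = data.astype(np.float64)
    return AudioBuffer(data, rate)


def write_wav(path: str | Path, buf: AudioBuffer, fmt: str = "float32") -> None:
    """Write a buffer as WAV; ``fmt`` is ``"float32"`` (default) or ``"pcm16"``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "float32":
        wavfile.write(path, buf.rate, buf.samples.astype(np.float32))
    elif fmt == "pcm16":
        clipped = np.clip(buf.samples, -1.0, 32767 / 32768)
        wavfile.write(path, buf.rate, np.round(clipped * 32768).astype(np.int16))
    else:
        raise ValueError(f"unknown WAV format {fmt!r} (use 'float32' or 'pcm16')")
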