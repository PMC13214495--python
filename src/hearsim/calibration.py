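"""Digital-to-acoustic calibration and Speechmap-style verification.

A :class:`CalibrationMap` is an affine link between digital RMS (dBFS)
and acoustic level (dB SPL) at a given playback volume setting:

    level(x) = full_scale_spl + 20*log10(RMS(x)) - step_db*(100 - volume)

The default map anchors the packaged conversational-speech fixture at
the default volume setting (20/100) to 63.5 dB SPL, the center of the
conversational-speech window used for calibration, with 0.5 dB of
attenuation per volume step below full volume.

:func:`compute_ltass` measures third-octave long-term average speech
spectra with the dynamic speech range (30th/99th percentile short-term
band levels), and :func:`verify_chain` renders a simulation chain and
checks its output levels against expectation — the software analogue of
a real-ear Speechmap check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import get_window

from .audiogram import Audiogram, interpolate_to_bands
from .buffer import AudioBuffer

#: Digital RMS of packaged fixtures at their default level.
DEFAULT_FIXTURE_RMS = 0.05
#: Default tablet-style volume setting (out of 100).
DEFAULT_VOLUME = 20
#: Conversational-speech anchor: center of the 62-65 dB SPL window.
CONVERSATIONAL_SPL = 63.5

#: ANSI nominal third-octave band centers, 125 Hz - 8 kHz.
THIRD_OCTAVE_NOMINAL = (
    125, 160, 200, 250, 315, 400, 500, 630, 800, 1000,
    1250, 1600, 2000, 2500, 3150, 4000, 5000, 6300, 8000,
)
# Exact base-2 centers (1000 * 2^(k/3)) used for band-edge arithmetic.
_THIRD_OCTAVE_EXACT = tuple(1000.0 * 2.0 ** (k / 3.0) for k in range(-9, 10))


@dataclass(frozen=True)
class CalibrationMap:
    """Affine dBFS-to-dB-SPL map with a stepped volume model.

    ``full_scale_spl`` is the dB SPL produced by a 0 dBFS RMS signal at
    full volume; each volume step below 100 attenuates by
    ``step_db`` dB.  Raising the volume setting never lowers the level.
    """

    full_scale_spl: float
    volume: int = DEFAULT_VOLUME
    step_db: float = 0.5

    def __post_init__(self) -> None:
        if not 70.0 <= self.full_scale_spl <= 140.0:
            raise ValueError(
                f"full_scale_spl {self.full_scale_spl} outside [70, 140] dB SPL"
            )
        if self.step_db < 0:
            raise ValueError("volume step attenuation must be >= 0 dB")
        if not 0 <= self.volume <= 100:
            raise ValueError("volume setting must be in [0, 100]")

    @property
    def attenuation_db(self) -> float:
        return self.step_db * (100 - self.volume)

    def spl_from_rms(self, rms: float) -> float:
        if rms <= 0:
            raise ValueError("cannot express silence (RMS = 0) in dB SPL")
        return self.full_scale_spl + 20.0 * math.log10(rms) - self.attenuation_db

    def spl_from_power(self, mean_square) -> np.ndarray:
        """Vector form on mean-square power (floored at -400 dB)."""
        p = np.maximum(np.asarray(mean_square, dtype=float), 1e-40)
        return self.full_scale_spl + 10.0 * np.log10(p) - self.attenuation_db

    def rms_for_spl(self, spl: float) -> float:
        """Digital RMS that measures at the requested dB SPL under this map."""
        return 10.0 ** ((spl - self.full_scale_spl + self.attenuation_db) / 20.0)

    def with_volume(self, volume: int) -> "CalibrationMap":
        return CalibrationMap(self.full_scale_spl, volume=volume, step_db=self.step_db)


def default_calibration() -> CalibrationMap:
    """Map anchoring the default fixture (RMS 0.05, volume 20) to 63.5 dB SPL."""
    offset = (
        CONVERSATIONAL_SPL
        + 0.5 * (100 - DEFAULT_VOLUME)
        - 20.0 * math.log10(DEFAULT_FIXTURE_RMS)
    )
    return CalibrationMap(full_scale_spl=offset, volume=DEFAULT_VOLUME, step_db=0.5)


def measure_spl(x: AudioBuffer, calib: CalibrationMap) -> float:
    """Broadband RMS level of a buffer in dB SPL."""
    rms = x.rms()
    if rms <= 0:
        raise ValueError("silent input: broadband SPL is undefined")
    return calib.spl_from_rms(rms)


# -- LTASS ------------------------------------------------------------


@dataclass(frozen=True)
class LtassReport:
    """Third-octave long-term spectrum with dynamic speech range.

    ``ltass_spl`` is the long-term average band level; ``p30_spl`` and
    ``p99_spl`` are the 30th/99th percentile short-term (125 ms) band
    levels bracketing it — the dynamic range of running speech.
    """

    centers_hz: tuple
    ltass_spl: tuple
    p30_spl: tuple
    p99_spl: tuple
    broadband_spl: float
    frame_ms: float = 125.0

    def as_rows(self) -> list[dict]:
        return [
            {"center_hz": c, "ltass_spl": l, "p30_spl": lo, "p99_spl": hi}
            for c, l, lo, hi in zip(self.centers_hz, self.ltass_spl, self.p30_spl, self.p99_spl)
        ]


def third_octave_bands(rate: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nominal centers plus exact lower/upper band edges that fit below Nyquist."""
    nominal, lo, hi = [], [], []
    for nom, exact in zip(THIRD_OCTAVE_NOMINAL, _THIRD_OCTAVE_EXACT):
        upper = exact * 2 ** (1 / 6)
        if upper > rate / 2:
            break
        nominal.append(float(nom))
        lo.append(exact * 2 ** (-1 / 6))
        hi.append(upper)
    return np.array(nominal), np.array(lo), np.array(hi)


def _frame_band_powers(
    x: np.ndarray, rate: int, frame_len: int, hop: int, lo: np.ndarray, hi: np.ndarray
) -> np.ndarray:
    """Mean-square power per (frame, band) from windowed periodograms."""
    n_frames = 1 + (len(x) - frame_len) // hop
    frames = np.lib.stride_tricks.sliding_window_view(x, frame_len)[::hop][:n_frames]
    w = get_window("hann", frame_len, fftbins=True)
    spec = np.fft.rfft(frames * w, axis=1)
    # Scale so that band powers sum to the frame's mean-square value.
    p = np.abs(spec) ** 2
    p[:, 1:] *= 2.0
    if frame_len % 2 == 0:
        p[:, -1] /= 2.0
    p /= frame_len * np.sum(w**2)
    freqs = np.fft.rfftfreq(frame_len, d=1.0 / rate)
    bands = np.empty((n_frames, len(lo)))
    for b, (f0, f1) in enumerate(zip(lo, hi)):
        sel = (freqs >= f0) & (freqs < f1)
        bands[:, b] = p[:, sel].sum(axis=1)
    return bands


def compute_ltass(
    x: AudioBuffer,
    calib: CalibrationMap,
    frame_ms: float = 125.0,
    overlap: float = 0.5,
    percentiles: tuple[float, float] = (30.0, 99.0),
) -> LtassReport:
    """Third-octave LTASS with dynamic speech range.

    Short-term band levels are measured in 125 ms half-overlapping
    Hann-windowed frames; the long-term level is the dB of the mean
    linear band power over frames, and the dynamic-range curves are the
    requested percentiles of the short-term levels.  Requires at least
    5 s of material for a stable long-term average.
    """
    mono = x.to_mono()
    if mono.duration < 5.0:
        raise ValueError(
            f"LTASS needs >= 5 s of material, got {mono.duration:.2f} s"
        )
    nominal, lo, hi = third_octave_bands(mono.rate)
    frame_len = int(round(frame_ms * 1e-3 * mono.rate))
    hop = max(1, int(round(frame_len * (1.0 - overlap))))
    bands = _frame_band_powers(mono.samples, mono.rate, frame_len, hop, lo, hi)
    ltass = calib.spl_from_power(bands.mean(axis=0))
    frame_levels = calib.spl_from_power(bands)
    p_lo = np.percentile(frame_levels, percentiles[0], axis=0)
    p_hi = np.percentile(frame_levels, percentiles[1], axis=0)
    return LtassReport(
        centers_hz=tuple(nominal),
        ltass_spl=tuple(ltass),
        p30_spl=tuple(p_lo),
        p99_spl=tuple(p_hi),
        broadband_spl=measure_spl(mono, calib),
        frame_ms=frame_ms,
    )


def band_levels_spl(x: AudioBuffer, calib: CalibrationMap) -> tuple[np.ndarray, np.ndarray]:
    """Long-term third-octave band levels (no duration floor); (centers, dB SPL)."""
    mono = x.to_mono()
    nominal, lo, hi = third_octave_bands(mono.rate)
    frame_len = int(round(0.125 * mono.rate))
    frame_len = min(frame_len, mono.n_samples)
    bands = _frame_band_powers(mono.samples, mono.rate, frame_len, frame_len // 2 or 1, lo, hi)
    return nominal, calib.spl_from_power(bands.mean(axis=0))


# -- chain verification ----------------------------------------------


@dataclass(frozen=True)
class VerificationCheck:
    name: str
    passed: bool
    detail: str


@dataclass(frozen=True)
class VerificationReport:
    """Speechmap-style report: per-stage LTASS plus pass/fail checks."""

    checks: tuple = field(default=())
    stages: dict = field(default_factory=dict)  # stage name -> LtassReport

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def summary(self) -> str:
        lines = []
        for c in self.checks:
            lines.append(f"[{'PASS' if c.passed else 'FAIL'}] {c.name}: {c.detail}")
        return "\n".join(lines)


def verify_chain(
    source: AudioBuffer,
    ag: Audiogram,
    mode: str,
    scenario,
    calib: CalibrationMap,
    band_tol_db: float = 2.0,
) -> VerificationReport:
    """Render a chain and verify audibility across frequencies.

    Measures SPL and third-octave levels at the environment output and
    at the profile output, then checks: the conversational input window
    (62-65 dB SPL) when the source is at the calibrated level; for the
    unaided profile, that per-band attenuation matches the interpolated
    thresholds within ``band_tol_db`` over the 250 Hz - 8 kHz mid-bands;
    for the aided profile, that aided band levels are at least the
    unaided ones wherever there is hearing loss.
    """
    from .environment import apply_environment
    from .hearing_aid import simulate_aided
    from .hearing_loss import simulate_unaided

    checks: list[VerificationCheck] = []
    stages: dict[str, LtassReport] = {}

    mono = source.to_mono()
    staged = apply_environment(mono, scenario)
    stages["input"] = compute_ltass(staged, calib)
    in_spl = stages["input"].broadband_spl

    if mode == "normal":
        rendered = staged.to_stereo()
    elif mode == "unaided":
        rendered = simulate_unaided(staged, ag)
    elif mode == "aided":
        rendered = simulate_aided(staged, ag, calib)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    for chan, earname in ((0, "left"), (1, "right")):
        stages[f"output_{earname}"] = compute_ltass(rendered.channel(chan), calib)

    if getattr(scenario, "kind", "quiet") == "quiet":
        checks.append(
            VerificationCheck(
                "conversational_input_level",
                62.0 <= in_spl <= 65.0,
                f"input {in_spl:.2f} dB SPL (target window 62-65)",
            )
        )

    centers = np.asarray(stages["input"].centers_hz)
    mid = (centers >= 250.0) & (centers <= 8000.0)
    if mode == "normal":
        d = np.asarray(stages["output_left"].ltass_spl) - np.asarray(stages["input"].ltass_spl)
        worst = float(np.max(np.abs(d[mid])))
        checks.append(
            VerificationCheck(
                "identity_band_levels",
                worst <= 0.5,
                f"max band deviation {worst:.3f} dB (tol 0.5)",
            )
        )
    elif mode == "unaided":
        for earname in ("left", "right"):
            drop = np.asarray(stages["input"].ltass_spl) - np.asarray(
                stages[f"output_{earname}"].ltass_spl
            )
            hl = interpolate_to_bands(ag, earname, centers)
            worst = float(np.max(np.abs(drop[mid] - hl[mid])))
            checks.append(
                VerificationCheck(
                    f"attenuation_matches_thresholds_{earname}",
                    worst <= band_tol_db,
                    f"max |attenuation - HL| {worst:.2f} dB over 250-8000 Hz "
                    f"(tol {band_tol_db})",
                )
            )
    elif mode == "aided":
        unaided = simulate_unaided(staged, ag)
        for chan, earname in ((0, "left"), (1, "right")):
            aided_l = np.asarray(stages[f"output_{earname}"].ltass_spl)
            una = compute_ltass(unaided.channel(chan), calib)
            hl = interpolate_to_bands(ag, earname, centers)
            sel = mid & (hl > 0)
            gain = aided_l - np.asarray(una.ltass_spl)
            ok = bool(np.all(gain[sel] > 0)) if sel.any() else True
            checks.append(
                VerificationCheck(
                    f"aided_audibility_gain_{earname}",
                    ok,
                    f"min aided-vs-unaided band gain "
                    f"{float(gain[sel].min()) if sel.any() else 0.0:+.2f} dB where HL > 0",
                )
            )

    for name, rep in stages.items():
        lo_ok = np.all(np.asarray(rep.p30_spl) <= np.asarray(rep.ltass_spl) + 1e-9)
        hi_ok = np.all(np.asarray(rep.ltass_spl) <= np.asarray(rep.p99_spl) + 1e-9)
        checks.append(
            VerificationCheck(
                f"dynamic_range_brackets_ltass_{name}",
                bool(lo_ok and hi_ok),
                "p30 <= LTASS <= p99 per band",
            )
        )
    return VerificationReport(checks=tuple(checks), stages=stages)
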