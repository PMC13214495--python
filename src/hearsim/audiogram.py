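"""Audiograms: per-ear hearing thresholds and their interpolation.

An audiogram records the softest audible level, in dB HL (hearing level:
elevation relative to average normal hearing), at a set of standard
audiometric frequencies, independently for each ear.  It is the sole
parameter of both the unaided-loss filter and the hearing-aid
prescription.

File format: JSON ``{"left": {"250": 15, ...}, "right": {...}}`` with
numeric-string frequency keys in ascending order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

#: Frequencies (Hz) every audiogram must contain.
REQUIRED_FREQUENCIES = (250.0, 500.0, 1000.0, 2000.0, 4000.0, 8000.0)
#: Optional inter-octave frequencies (Hz).
OPTIONAL_FREQUENCIES = (125.0, 750.0, 1500.0, 3000.0, 6000.0)

FREQ_RANGE_HZ = (125.0, 12000.0)
THRESHOLD_RANGE_DB_HL = (-10.0, 120.0)

EARS = ("left", "right")


def _validate_ear(name: str, points: Mapping[float, float]) -> dict[float, float]:
    freqs = [float(f) for f in points.keys()]
    if len(freqs) < 2:
        raise ValueError(f"{name} ear: need at least 2 frequency points, got {len(freqs)}")
    if any(b <= a for a, b in zip(freqs, freqs[1:])):
        raise ValueError(f"{name} ear: frequencies must be strictly ascending, got {freqs}")
    lo, hi = FREQ_RANGE_HZ
    for f in freqs:
        if not lo <= f <= hi:
            raise ValueError(f"{name} ear: frequency {f} Hz outside [{lo}, {hi}] Hz")
    out: dict[float, float] = {}
    tlo, thi = THRESHOLD_RANGE_DB_HL
    for f, t in points.items():
        t = float(t)
        if not np.isfinite(t) or not tlo <= t <= thi:
            raise ValueError(
                f"{name} ear: threshold {t} dB HL at {float(f)} Hz outside [{tlo}, {thi}] dB HL"
            )
        out[float(f)] = t
    return out


@dataclass(frozen=True)
class Audiogram:
    """Per-ear hearing thresholds (dB HL) at ascending frequencies (Hz).

    Ears may differ; each needs at least two points with frequencies in
    [125, 12000] Hz and thresholds in [-10, 120] dB HL.
    """

    left: Mapping[float, float]
    right: Mapping[float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "left", _validate_ear("left", self.left))
        object.__setattr__(self, "right", _validate_ear("right", self.right))

    def ear(self, which: str) -> dict[float, float]:
        if which not in EARS:
            raise ValueError(f"ear must be one of {EARS}, got {which!r}")
        return dict(getattr(self, which))

    def frequencies(self, which: str) -> np.ndarray:
        return np.array(sorted(self.ear(which)), dtype=float)

    def thresholds(self, which: str) -> np.ndarray:
        e = self.ear(which)
        return np.array([e[f] for f in sorted(e)], dtype=float)

    def is_normal(self) -> bool:
        """True when every threshold is 0 dB HL in both ears."""
        return all(t == 0.0 for e in EARS for t in self.ear(e).values())

    @staticmethod
    def flat(level_db_hl: float = 0.0) -> "Audiogram":
        """Symmetric flat audiogram at the given level across the required set."""
        pts = {f: float(level_db_hl) for f in REQUIRED_FREQUENCIES}
        return Audiogram(left=pts, right=dict(pts))


@dataclass(frozen=True)
class BandGains:
    """Per-band gain in dB at ascending center frequencies (Hz)."""

    centers: tuple = field(default=())
    gains: tuple = field(default=())

    def __post_init__(self) -> None:
        c = tuple(float(x) for x in self.centers)
        g = tuple(float(x) for x in self.gains)
        if len(c) != len(g):
            raise ValueError(f"centers ({len(c)}) and gains ({len(g)}) must match in length")
        if len(c) == 0:
            raise ValueError("BandGains needs at least one band")
        if any(b <= a for a, b in zip(c, c[1:])):
            raise ValueError("band centers must be strictly ascending")
        if not all(np.isfinite(g)):
            raise ValueError("gains must be finite")
        object.__setattr__(self, "centers", c)
        object.__setattr__(self, "gains", g)


# -- file I/O ---------------------------------------------------------


def _parse_ear_json(name: str, obj: object) -> dict[float, float]:
    if not isinstance(obj, dict) or not obj:
        raise ValueError(f"audiogram field {name!r} must be a non-empty object")
    allowed = set(REQUIRED_FREQUENCIES) | set(OPTIONAL_FREQUENCIES)
    pts: dict[float, float] = {}
    for key, val in obj.items():
        try:
            f = float(key)
        except (TypeError, ValueError):
            raise ValueError(f"{name} ear: frequency key {key!r} is not numeric") from None
        if f not in allowed:
            raise ValueError(
                f"{name} ear: frequency {f:g} Hz is not a standard audiometric frequency "
                f"(allowed: {sorted(allowed)})"
            )
        if not isinstance(val, (int, float)) or isinstance(val, bool):
            raise ValueError(f"{name} ear: threshold for {f:g} Hz must be a number, got {val!r}")
        pts[f] = float(val)
    missing = sorted(set(REQUIRED_FREQUENCIES) - set(pts))
    if missing:
        raise ValueError(f"{name} ear: missing required frequencies {[int(m) for m in missing]} Hz")
    return pts


def load_audiogram(path: str | Path) -> Audiogram:
    """Read and validate an audiogram JSON file.

    The required octave frequencies 250-8000 Hz must all be present per
    ear; the inter-octave frequencies 125/750/1500/3000/6000 Hz are
    optional.  Frequency keys must be written in ascending order.
    """
    path = Path(path)
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(data, dict):
        raise ValueError(f"{path}: top level must be an object with 'left'/'right'")
    for earname in EARS:
        if earname not in data:
            raise ValueError(f"{path}: missing ear {earname!r}")
        keys = [float(k) for k in data[earname]]
        if keys != sorted(keys):
            raise ValueError(f"{path}: {earname} ear frequencies are not in ascending order")
    return Audiogram(
        left=_parse_ear_json("left", data["left"]),
        right=_parse_ear_json("right", data["right"]),
    )


def save_audiogram(ag: Audiogram, path: str | Path) -> None:
    """Write an audiogram as JSON with ascending numeric-string keys."""

    def fmt(f: float) -> str:
        return str(int(f)) if f == int(f) else str(f)

    payload = {
        earname: {fmt(f): ag.ear(earname)[f] for f in sorted(ag.ear(earname))}
        for earname in EARS
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


# -- presets ----------------------------------------------------------

# Registered as plain data so alternative configurations can be dropped in.
_PRESETS: dict[str, dict[float, float]] = {
    "normal": {f: 0.0 for f in REQUIRED_FREQUENCIES},
    # Mild-sloping-to-severe presbycusis shape, symmetric ears.
    "sloping_snhl": {
        250.0: 15.0,
        500.0: 20.0,
        1000.0: 30.0,
        2000.0: 45.0,
        4000.0: 60.0,
        8000.0: 70.0,
    },
}


def preset_names() -> tuple[str, ...]:
    return tuple(sorted(_PRESETS))


def preset(name: str) -> Audiogram:
    """Return a registered audiogram preset (symmetric ears).

    ``"normal"`` is all-zero; ``"sloping_snhl"`` is a sloping
    sensorineural configuration rising from 15 dB HL at 250 Hz to
    70 dB HL at 8 kHz.
    """
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {', '.join(preset_names())}")
    pts = dict(_PRESETS[name])
    return Audiogram(left=pts, right=dict(pts))


def random_audiogram(
    rng: np.random.Generator,
    max_slope_db_per_oct: float = 20.0,
    max_hl_db: float = 90.0,
) -> Audiogram:
    """Draw a clinically plausible sensorineural audiogram.

    Shapes are sampled from the common configurations — flat, gently or
    steeply sloping, reverse-slope, with an occasional 4 kHz notch —
    with per-frequency jitter, thresholds clipped to [0, ``max_hl_db``]
    dB HL and adjacent-octave changes limited to
    ``max_slope_db_per_oct`` (precipitously sloping losses beyond that
    are outside the family).  The right ear is the left with up to
    ±8 dB of asymmetry.
    """
    freqs = np.asarray(REQUIRED_FREQUENCIES)
    oct_pos = np.log2(freqs / freqs[0])
    slope_ranges = {
        "flat": (-4.0, 4.0),
        "gently_sloping": (5.0, 12.0),
        "steeply_sloping": (12.0, max_slope_db_per_oct),
        "reverse": (-15.0, -5.0),
    }
    kind = rng.choice(list(slope_ranges), p=[0.3, 0.35, 0.2, 0.15])
    slope = rng.uniform(*slope_ranges[kind])
    base = rng.uniform(0.0, 50.0)

    def shape(jitter: np.ndarray) -> dict[float, float]:
        t = base + slope * oct_pos + jitter
        if rng.uniform() < 0.25:
            t[freqs == 4000.0] += rng.uniform(5.0, 15.0)
        steps = np.clip(np.diff(t), -max_slope_db_per_oct, max_slope_db_per_oct)
        t = np.clip(np.concatenate([[t[0]], t[0] + np.cumsum(steps)]), 0.0, max_hl_db)
        return {float(f): float(v) for f, v in zip(freqs, t)}

    left = shape(rng.uniform(-3.0, 3.0, freqs.size))
    right = shape(rng.uniform(-3.0, 3.0, freqs.size) + rng.uniform(-8.0, 8.0))
    return Audiogram(left=left, right=right)


# -- interpolation ----------------------------------------------------


def interpolate_to_bands(ag: Audiogram, ear: str, centers) -> np.ndarray:
    """Interpolate an ear's thresholds (dB HL) onto band center frequencies.

    Linear interpolation of dB HL against log2(frequency) — the audiogram
    plotting convention — with flat (nearest-endpoint) extrapolation
    outside the audiogram's frequency span.

    Parameters
    ----------
    ear : {"left", "right"}
    centers : array-like of float
        Ascending frequencies in [50, 16000] Hz.

    Returns
    -------
    ndarray of threshold values (dB HL), one per center.
    """
    centers = np.asarray(centers, dtype=float)
    if centers.size == 0:
        raise ValueError("centers must be non-empty")
    if np.any(np.diff(centers) <= 0):
        raise ValueError("centers must be strictly ascending")
    if centers.min() < 50.0 or centers.max() > 16000.0:
        raise ValueError("centers must lie within [50, 16000] Hz")
    freqs = ag.frequencies(ear)
    thr = ag.thresholds(ear)
    # np.interp clamps to endpoint values outside the data span.
    return np.interp(np.log2(centers), np.log2(freqs), thr)
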