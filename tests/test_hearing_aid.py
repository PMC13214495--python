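import math

import numpy as np
import pytest

from hearsim.audiogram import Audiogram, preset
from hearsim.buffer import AudioBuffer
from hearsim.calibration import default_calibration
from hearsim.hearing_aid import (
    CompressorParams,
    compress,
    prescribe,
    simulate_aided,
    static_io_curve,
)

from .conftest import make_gated_tone

FREQS = (250.0, 500.0, 1000.0, 2000.0, 4000.0, 8000.0)


def single_channel_params(g65=20.0, ratio=2.0, knee=40.0, ceiling=105.0, rate=44100):
    return CompressorParams(edges=(0.0, rate / 2.0), knee_spl=(knee,), ratio=(ratio,),
                            gain65=(g65,), ceiling_spl=(ceiling,))


class TestPrescribe:
    def test_no_loss_is_transparent(self):
        p = prescribe(preset("normal"), "left")
        assert all(g == 0.0 for g in p.gain65)
        assert all(r == 1.0 for r in p.ratio)

    def test_half_gain_rule_values(self):
        ag = Audiogram(left={f: 60.0 for f in FREQS}, right={f: 60.0 for f in FREQS})
        p = prescribe(ag, "left")
        assert all(g == pytest.approx(30.0) for g in p.gain65)
        assert all(r == pytest.approx(1.6) for r in p.ratio)
        assert all(k == 40.0 for k in p.knee_spl)
        assert all(c == 105.0 for c in p.ceiling_spl)

    def test_sloping_preset_gain_rises_with_frequency(self):
        p = prescribe(preset("sloping_snhl"), "left")
        assert all(b >= a for a, b in zip(p.gain65, p.gain65[1:]))
        assert p.gain65[-1] > p.gain65[0]

    def test_unknown_rule_rejected(self):
        with pytest.raises(KeyError, match="dsl_like_halfgain"):
            prescribe(preset("normal"), "left", rule="nal_nl9")

    def test_six_octave_channels(self):
        p = prescribe(preset("normal"), "left", rate=44100)
        assert p.n_channels == 6
        assert p.edges[1:-1] == (250.0, 500.0, 1000.0, 2000.0, 4000.0)


class TestStaticCurve:
    def test_linear_when_ratio_one(self):
        p = single_channel_params(g65=12.0, ratio=1.0)
        for level in (30.0, 50.0, 65.0, 90.0):
            assert static_io_curve(p, 0, level) == pytest.approx(level + 12.0)

    def test_slope_above_knee(self):
        p = single_channel_params(g65=10.0, ratio=2.0, knee=40.0)
        at65 = static_io_curve(p, 0, 65.0)
        assert at65 == pytest.approx(75.0)
        assert static_io_curve(p, 0, 85.0) == pytest.approx(at65 + 10.0)

    def test_ceiling_caps_output(self):
        p = single_channel_params(g65=40.0, ratio=1.5, ceiling=105.0)
        assert static_io_curve(p, 0, 110.0) == pytest.approx(105.0)

    def test_randomized_curves_continuous_monotone_correct_slope(self):
        """Finite-difference oracle: slope 1 below knee, 1/CR above, curve
        continuous and non-decreasing over [0, 120] dB SPL."""
        rng = np.random.default_rng(3)
        for _ in range(25):
            p = single_channel_params(
                g65=float(rng.uniform(0, 45)),
                ratio=float(rng.uniform(1.0, 3.0)),
                knee=float(rng.uniform(20, 60)),
                ceiling=float(rng.uniform(95, 120)),
            )
            grid = np.linspace(0.0, 120.0, 2401)
            out = np.array([static_io_curve(p, 0, g) for g in grid])
            diffs = np.diff(out) / np.diff(grid)
            assert np.all(diffs >= -1e-9), "curve must be non-decreasing"
            assert np.max(np.abs(np.diff(out))) < 0.06, "curve must be continuous"
            above = (grid[:-1] > p.knee_spl[0] + 0.5) & (out[1:] < p.ceiling_spl[0] - 0.5)
            if above.any():
                assert np.allclose(diffs[above], 1.0 / p.ratio[0], atol=1e-6)
            below = grid[1:] < p.knee_spl[0] - 0.5
            if below.any():
                assert np.allclose(diffs[below], 1.0, atol=1e-6)


class TestCompressorParamsValidation:
    def test_ratio_below_one_rejected(self):
        with pytest.raises(ValueError, match=">= 1"):
            single_channel_params(ratio=0.8)

    def test_attack_must_precede_release(self):
        with pytest.raises(ValueError, match="attack"):
            CompressorParams(edges=(0.0, 22050.0), knee_spl=(40.0,), ratio=(1.0,),
                             gain65=(0.0,), ceiling_spl=(105.0,),
                             attack_ms=100.0, release_ms=5.0)

    def test_kneepoint_range_enforced(self):
        with pytest.raises(ValueError, match="knee"):
            single_channel_params(knee=10.0)


class TestCompress:
    def test_transparent_params_are_identity(self, speech_short, calib):
        p = prescribe(preset("normal"), "left", rate=speech_short.rate)
        y = compress(speech_short, p, calib)
        assert np.max(np.abs(y.samples - speech_short.samples)) < 1e-4

    def test_steady_tone_follows_static_curve_at_anchor(self, calib):
        p = single_channel_params(g65=20.0, ratio=2.0)
        x = make_gated_tone(1000.0, calib.rms_for_spl(65.0))
        y = compress(x, p, calib)
        seg = y.samples[int(0.25 * 44100):int(0.45 * 44100)]
        out_spl = calib.spl_from_rms(float(np.sqrt(np.mean(seg**2))))
        assert out_spl == pytest.approx(85.0, abs=0.5)

    def test_steady_state_matches_static_curve_across_sweep(self, calib):
        """Oracle sweep: 45-95 dB SPL tones at each channel center settle to
        the static I/O curve within 0.5 dB."""
        p = prescribe(preset("sloping_snhl"), "left", rate=44100)
        for ch, fc in enumerate(p.channel_centers()):
            for level in (45.0, 65.0, 95.0):
                x = make_gated_tone(fc, calib.rms_for_spl(level))
                y = compress(x, p, calib)
                seg = y.samples[int(0.25 * 44100):int(0.45 * 44100)]
                out_spl = calib.spl_from_rms(float(np.sqrt(np.mean(seg**2))))
                assert out_spl == pytest.approx(static_io_curve(p, ch, level), abs=0.5)

    def test_step_response_matches_scalar_oracle(self, calib):
        """A 50->80 dB SPL tone step, single channel, CR=2: the output level
        trace matches an independent per-sample scalar implementation of the
        same detector/gain model within 0.5 dB, and the post-step gain
        settles to the static curve within 3x the release time."""
        rate = 16000
        p = single_channel_params(g65=15.0, ratio=2.0, rate=rate)
        t_step = 0.5
        n = int(1.0 * rate)
        amp = np.where(np.arange(n) < t_step * rate,
                       math.sqrt(2) * calib.rms_for_spl(50.0),
                       math.sqrt(2) * calib.rms_for_spl(80.0))
        x = amp * np.sin(2 * np.pi * 1000.0 * np.arange(n) / rate)
        y = compress(AudioBuffer(x, rate), p, calib).samples

        # independent scalar oracle: same detector topology, per-sample python
        a = math.exp(-1.0 / (rate * 0.005))
        ca = math.exp(-1.0 / (rate * p.attack_ms * 1e-3))
        cr = math.exp(-1.0 / (rate * p.release_ms * 1e-3))
        s1 = s2 = 0.0
        env = None
        y_oracle = np.empty(n)
        for i, v in enumerate(x):
            pw = v * v
            s1 = a * s1 + (1 - a) * pw
            s2 = a * s2 + (1 - a) * s1
            env = s2 if env is None else (
                (ca if s2 > env else cr) * env + (1 - (ca if s2 > env else cr)) * s2)
            level = calib.spl_from_power(max(env, 1e-40))
            gain = min(static_io_curve(p, 0, float(level)) - float(level),
                       105.0 - float(level))
            y_oracle[i] = v * 10.0 ** (gain / 20.0)

        win = int(0.005 * rate)
        start = int(0.1 * rate)
        for i0 in range(start, n - win, win):
            lvl = calib.spl_from_rms(float(np.sqrt(np.mean(y[i0:i0 + win] ** 2))))
            lvl_o = calib.spl_from_rms(float(np.sqrt(np.mean(y_oracle[i0:i0 + win] ** 2))))
            assert abs(lvl - lvl_o) < 0.5

        settle = int((t_step + 3 * p.release_ms * 1e-3) * rate)
        seg = y[settle:settle + int(0.1 * rate)]
        out_spl = calib.spl_from_rms(float(np.sqrt(np.mean(seg**2))))
        assert out_spl == pytest.approx(static_io_curve(p, 0, 80.0), abs=0.5)

    def test_deterministic(self, speech_short, calib):
        p = prescribe(preset("sloping_snhl"), "left", rate=speech_short.rate)
        y1 = compress(speech_short, p, calib)
        y2 = compress(speech_short, p, calib)
        assert np.array_equal(y1.samples, y2.samples)


class TestSimulateAided:
    def test_no_loss_is_passthrough(self, speech_short, calib):
        out = simulate_aided(speech_short, preset("normal"), calib)
        ref = speech_short.to_stereo()
        assert np.max(np.abs(out.samples - ref.samples)) < 1e-4

    def test_aided_between_unaided_and_normal(self, speech_short, calib):
        """Amplification improves audibility but does not restore normal
        hearing: unaided RMS < aided RMS < normal RMS on the speech fixture."""
        from hearsim.hearing_loss import simulate_unaided

        ag = preset("sloping_snhl")
        normal = speech_short.to_stereo()
        unaided = simulate_unaided(speech_short, ag)
        aided = simulate_aided(speech_short, ag, calib)
        assert unaided.rms() < aided.rms() < normal.rms()

    def test_asymmetric_prescription_per_ear(self, speech_short, calib):
        ag = Audiogram(left={f: 0.0 for f in FREQS}, right={f: 50.0 for f in FREQS})
        out = simulate_aided(speech_short, ag, calib)
        left, right = out.channel_rms()
        # left ear transparent; right ear aided-through-loss, still quieter
        assert 20 * np.log10(left / speech_short.rms()) == pytest.approx(0.0, abs=0.05)
        assert right < left
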