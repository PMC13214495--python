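# hearsim

An offline hearing-loss and hearing-aid listening simulator for
audiology education and counseling. Given an audio signal and a two-ear
audiogram, `hearsim` renders calibrated stereo demonstrations of three
listening profiles — **normal hearing**, **unaided hearing loss**, and
**aided** (hearing-aid-amplified sound heard *through* the loss) —
across four listening environments: speech in quiet, speech in
background noise at an adjustable SNR, speech at a talker distance, and
instrumental music. A calibration subsystem anchors digital levels to
dB SPL and produces Speechmap-style LTASS verification reports.

The intended users are hearing-care professionals, trainees, and
researchers who want reproducible, file-based simulations of what a
person with a given audiogram hears, without specialized hardware.

## The model

**Unaided loss.** Hearing loss is modeled as pure intensity attenuation:
at every frequency the signal is reduced by the threshold elevation,

    gain_dB(f) = −HL(f),

where HL(f) interpolates the ear's audiogram (dB HL vs log₂ f, flat
beyond the measured span). The filter is applied per ear through a
zero-phase STFT filterbank (√Hann analysis/synthesis, 75% overlap),
which reconstructs exactly at unity gain. No recruitment or distortion
is modeled — audibility only.

**Aided profile.** A prescriptive rule maps the audiogram to per-channel
wide dynamic range compression (6 channels, octave edges from 250 Hz).
The default `dsl_like_halfgain` rule prescribes

    G65 = clamp(HL/2, 0, 50) dB,   CR = clamp(1 + HL/100, 1, 3),

with a 40 dB SPL kneepoint and a 105 dB SPL output ceiling. Each
channel's envelope (attack 5 ms, release 100 ms, tracked in dB SPL via
the calibration map) drives gain along the static input/output curve:
slope 1 below the knee, 1/CR above, passing through (65, 65 + G65). The
compressed signal is then passed through the loss filter, so
amplification improves audibility but does not restore normal hearing.

**Environments.** Background noise is scaled so the speech-to-noise RMS
ratio equals the requested SNR. Talker distance follows the inverse
square law, −20·log₁₀(d/d_ref) dB (reference 1 m); noise is ambient and
is not distance-scaled, so distance degrades the effective SNR.

**Calibration.** An affine map links digital RMS to dB SPL with a
stepped volume model; the default anchors the packaged conversational
speech fixture at volume 20/100 to 63.5 dB SPL. `compute_ltass` measures
third-octave long-term average speech spectra with the 30th/99th
percentile dynamic speech range.

All test material is synthesized (speech-shaped modulated noise,
babble, pure tones, arpeggiated music stand-in), bit-reproducible from
a seed — no recordings are required or distributed.

## Worked example

Compare the three profiles for the built-in sloping sensorineural
preset (15 → 70 dB HL from 250 Hz to 8 kHz) on conversational speech in
quiet:

```sh
hearsim compare --fixture speech_shaped --audiogram preset:sloping_snhl
```

```
        environment  broadband_spl  delta_vs_normal_db  clipped_samples
mode
normal        quiet          63.50                0.00                0
unaided       quiet          45.63              -17.87                0
aided         quiet          55.08               -8.42                0
```

Normal hearing receives the speech at its calibrated conversational
level (63.5 dB SPL). Unaided, the sloping loss removes 17.9 dB of
broadband level (much more in the high bands). Aided, the half-gain
prescription recovers about 9.4 dB — louder than unaided, still 8.4 dB
short of normal.

The Speechmap-style verification chain checks the engine the way a
real-ear measurement would:

```sh
hearsim verify --audiogram preset:sloping_snhl --mode unaided
```

```
[PASS] conversational_input_level: input 63.50 dB SPL (target window 62-65)
[PASS] attenuation_matches_thresholds_left: max |attenuation - HL| 0.64 dB over 250-8000 Hz (tol 2.0)
[PASS] attenuation_matches_thresholds_right: max |attenuation - HL| 0.64 dB over 250-8000 Hz (tol 2.0)
[PASS] dynamic_range_brackets_ltass_input: p30 <= LTASS <= p99 per band
...
```

Other subcommands: `hearsim render` (write one demonstration to WAV +
JSON sidecar), `hearsim fixtures` (list/synthesize signals),
`hearsim presets`. Everything is also available as a library:

```python
import hearsim as hs

ag = hs.preset("sloping_snhl")
calib = hs.default_calibration()
speech = hs.generate_fixture("speech_shaped", duration=5.0, seed=7)
aided = hs.simulate_aided(speech, ag, calib)   # stereo AudioBuffer
print(hs.measure_spl(aided.channel(0), calib))
```

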