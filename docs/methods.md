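# Methods

This note documents the models, parameter choices, and numerical
decisions behind `hearsim`, and what the synthetic test material does
and does not establish about real-world behavior.

## Audiograms

An audiogram stores per-ear thresholds in dB HL at the standard
audiometric octave frequencies 250–8000 Hz (required) and the
inter-octaves 125/750/1500/3000/6000 Hz (optional). Ears are fully
independent. Thresholds are interpolated linearly in dB HL against
log₂(frequency) — the convention of audiogram plots — with flat
(nearest-endpoint) extrapolation outside the measured span, so the
simulator never extrapolates a loss steeper than observed.

The `sloping_snhl` preset (15/20/30/45/60/70 dB HL at
250/500/1k/2k/4k/8k, symmetric) is a typical
mild-sloping-to-severe presbycusis configuration; it is registered as
plain data and trivially replaceable.

`random_audiogram` draws from a parametric clinical family used by the
property tests and the acceptance script: flat, gently sloping
(5–12 dB/oct), steeply sloping (12–20 dB/oct), or reverse-slope shapes,
with per-frequency jitter, an occasional 4 kHz notch, up to ±8 dB ear
asymmetry, thresholds clipped to [0, 90] dB HL, and adjacent-octave
changes limited to 20 dB — the audiological boundary for
"precipitously sloping" loss. The cap is also a measurement-validity
condition: when an audiogram kinks more steeply than ~20 dB/octave
*inside* a third-octave analysis band, the band's energy-weighted
attenuation geometrically cannot equal the threshold at band center
(the discrepancy exceeds 2 dB at 30 dB/oct regardless of filter
resolution), so attenuation-fidelity statements are made over this
family.

## Unaided loss filter

The loss model is `gain_dB(f) = −HL(f)`: pure intensity attenuation
with no loudness recruitment, spectral smearing, or temporal
distortion. This is a deliberate scope decision — the simulation
demonstrates audibility decrements across frequency, not the full
perceptual consequences of cochlear damage, and listeners familiar
with real hearing loss will notice the absence of distortion.

Realization: an STFT filterbank with square-root Hann analysis and
synthesis windows at 75% overlap (COLA-exact; unity-gain round trip
reconstructs to machine precision), FFT size 2048 at 44.1/48 kHz and
1024 at lower rates. Per-bin real gains are interpolated from the
audiogram curve in dB vs log₂ f; the DC bin takes the lowest band's
gain. Real bin gains give a zero-phase response; the STFT's uniform
latency is removed by edge padding and trimming. The realized transfer
function matches the ideal interpolated curve to within about 1 dB even
at 60+ dB attenuations (verified by impulse-response measurement); a
small time-aliasing ripple (~0.01 dB) around the ideal response is the
reason the band-energy monotonicity property is asserted with 0.01 dB
slack rather than exactly.

Samples exceeding full scale after processing are hard-clipped and
counted; the count is logged and reported in render sidecars.
Attenuation-dominated paths essentially never clip; aided paths may.

## Hearing-aid stage

The prescription registry maps an audiogram to per-channel WDRC
parameters. True DSL v5.0 coefficient tables are proprietary, so the
shipped rule, `dsl_like_halfgain`, is a self-contained classic
half-gain rule with loss-dependent compression:
G65 = clamp(HL/2, 0, 50) dB, CR = clamp(1 + HL/100, 1, 3), kneepoint
40 dB SPL, ceiling 105 dB SPL. It preserves the qualitative fitting
contract — gain wherever there is loss, under-compensation relative to
normal hearing — and a table-driven rule can be registered by name
without touching the engine.

Six compression channels with octave-spaced edges at
250/500/1000/2000/4000 Hz (outer edges DC and Nyquist); attack 5 ms,
release 100 ms — typical commercial WDRC values. Channel thresholds are
interpolated at each channel's geometric-mean frequency.

The band split is a set of complementary zero-phase FIR filters:
channel *i* is the difference of Kaiser-window lowpasses (≈70 dB
stopband, transition 25% of the edge frequency capped at 400 Hz) at its
two edges, so the channels telescope to exactly the input when summed.
A brickwall STFT-mask split was rejected: its ~−40 dB leakage, after
+40 dB of prescribed gain in an otherwise-empty high channel, corrupts
steady-state levels by several dB; the FIR split keeps leakage near
−70 dB.

The level detector squares the band signal, smooths it with two
symmetric one-pole stages (5 ms) to strip carrier ripple — without
this, the asymmetric detector rides the ripple of low-frequency tones
and overreads by up to 2.4 dB — then applies the attack/release
one-pole (fast coefficient upward, slow downward) and converts to
dB SPL through the calibration map, so kneepoint and ceiling have
acoustic meaning. Both smoothers have unity DC gain: for steady tones
the envelope converges to the exact mean square, and measured
steady-state levels match the static I/O curve to ≲0.05 dB across the
45–95 dB SPL range (the acceptance tolerance is 0.5 dB).

The aided path is compression **then** the ear's loss filter: aided
sound is heard through the impaired ear. With the half-gain rule this
yields the ordering unaided < aided < normal in RMS on speech at
conversational level wherever HL > 0. No microphone/receiver bandwidth
limit is imposed; high-frequency sparseness of aided music arises from
the loss filter itself.

## Environments

`mix_at_snr` defines SNR on full-band RMS of the overlapping segment;
noise is trimmed, never looped, and the speech component is added
bit-exactly unscaled. Distance follows the inverse square law
(−20·log₁₀ d/d_ref, reference distance 1 m, 1 ft = 0.3048 m exactly).
Noise is ambient: in a combined noise+distance scenario the SNR is
defined at the reference distance and only the speech is
distance-scaled, so the effective SNR degrades by the distance
attenuation — the "hearing aids made it louder but it was still quiet
and noisy" demonstration. No reverberation, air absorption, or head
shadow is modeled; intensity only.

## Calibration and LTASS

`CalibrationMap` is affine in dB: `level = full_scale_spl +
20·log₁₀ RMS − step·(100 − volume)`, default 0.5 dB per volume step.
The default map anchors the packaged speech-shaped fixture (digital
RMS 0.05) at volume 20/100 to 63.5 dB SPL — the center of the 62–65
dB SPL conversational window the calibration check targets. Hardware
transfer functions are out of scope, so this anchor is definitional.
Broadband dB HL↔dB SPL conversion is identity (no per-frequency RETSPL
transform); the calibration is a broadband RMS anchor.

LTASS: 125 ms Hann frames at 50% overlap; band powers integrated into
third-octave bands (exact base-2 centers 1000·2^(k/3) for edge
arithmetic, ANSI nominal values reported), 125 Hz–8 kHz, truncated
below Nyquist. The long-term level is the dB of the mean linear frame
power; the dynamic speech range is the 30th/99th percentile of
short-term frame levels — common Speechmap practice. Frame percentiles
bracket the mean for the modulated fixtures used here; heavily gated
material (long true silences) could in principle push the mean below
p30, which the verification report would flag.

`verify_chain` renders a configuration and checks: conversational
input level within 62–65 dB SPL (quiet scenarios), per-band unaided
attenuation equal to interpolated HL within 2 dB over 250 Hz–8 kHz,
aided band levels above unaided wherever HL > 0, and per-stage
p30 ≤ LTASS ≤ p99.

## Synthetic signals

`speech_shaped`: Gaussian noise shaped flat over 100–500 Hz with a
−9 dB/octave density rolloff above 500 Hz (and a 12 dB/oct rolloff
below 100 Hz against rumble), amplitude-modulated at 4 Hz, depth 0.6 —
a stand-in for the long-term spectrum and syllabic envelope of running
speech. Note that a −9 dB/oct *density* slope appears as −6 dB/oct in
third-octave *band levels* (bandwidth grows +3.01 dB/oct); tests check
the bandwidth-normalized slope. `babble` sums 8 independently seeded
streams with random modulation phases. `music_tones` arpeggiates
harmonic tones across 262–3520 Hz. All fixtures are scaled to an exact
target RMS (default 0.05) and are bit-reproducible from a seed.

What passing tests show: the engine applies the documented gains,
levels, and orderings exactly on stationary-spectrum, speech-spectrum
material. What they do not show: intelligibility, naturalness, or the
perceptual fidelity of the simulation for real speech and music — the
fixtures have no phonetic structure, and the loss model deliberately
omits suprathreshold distortion.

## Problem sizes and tolerances

Default test material is 1–10 s at 44.1 kHz — long enough that
third-octave estimates at 250 Hz have negligible variance (input and
output are measured on the same noise realization, so gain estimates
are essentially exact), short enough that the whole suite runs in
seconds. Acceptance checks use 200 random audiograms, a 45–95 dB SPL
sweep in 5 dB steps per channel, and 100 random SNR pairs. Band-energy
oracles Hann-window the signal before the FFT: a rectangular window's
leakage floor (~−45 dB) cannot resolve 60 dB band attenuations.
Steady-state compressor levels are measured over 0.25–0.45 s of a
0.5 s gated tone (20 ms raised-cosine ramps), away from the gating
transients. WAV output is float32 by default so file round trips
preserve the 10⁻⁶-level passthrough contracts; PCM16 is available.

## Known limitations

- No recruitment, spectral smearing, or temporal-resolution modeling;
  no conductive-loss or bone-conduction handling; no tinnitus.
- The prescription is a documented stand-in, not DSL v5.0 table
  output; absolute aided levels should not be read as fitting targets.
- No room acoustics; distance is intensity-only.
- The calibration anchor is definitional (no hardware loop), so
  absolute dB SPL values describe the simulated playback chain, not a
  particular transducer.
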