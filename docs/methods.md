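# Methods

This note documents the models, numerical choices, and limitations behind
the package. All claims here are computed by the test suite or by
`scripts/acceptance.py`; nothing is asserted that the code does not
measure.

## Stimuli

**Analogue dyads.** Two sinusoids F1/F2 (80/120 Hz simulated; 220/330 Hz
nominal for the stepped device approximation) are superimposed or
interleaved in contiguous segments (200 μs simulated). The stepped device
dyad holds each of 72 steps of 126.26 μs constant per F0 period, pinning
the fundamental to 1/(72 × 126.26 μs) = 110.0023 Hz; the nominal F1/F2 are
rescaled proportionally (2·F0, 3·F0). Step values are the component
sinusoid at the step onset, optionally passed through an 8-bit uniform
mid-rise quantiser over [−A, +A] (the quantiser style is a documented
choice; only the resolution is fixed by the hardware). 33 periods give a
300-ms stimulus, 110 give 0.99998 s.

**AM pulse trains.** Symmetric biphasic pulses, 25 μs/phase, cathodic
leading, 8-μs inter-phase gap (zero in the simulation panels), at
per-train rate y (= F0 × 54 pulses per F0 period: 1998/2160/2322 pps for
F0 = 37/40/43 Hz). The sinusoidal amplitude modulation runs in linear
current from threshold T to most-comfortable level MCL; the modulator is
evaluated at each pulse's exact onset time and the whole pulse is scaled
by that one value, preserving per-pulse charge balance exactly (the
within-pulse envelope behaviour is not constrained by the hardware
description; constant-per-pulse is the simplest charge-safe choice).
Envelope phase is zero (sine) at stimulus onset and configurable; the
difference-frequency analysis is envelope-phase-invariant. Interleaving
offsets the second train by half a per-train period so every pulse falls
mid-way between two pulses of the other train: composite rate 2y
(4644 pps), 157-μs inter-pulse gap for 58-μs pulses.

**Sampling grid.** The simulation rate defaults to 1 MHz. Segment, phase,
and gap durations must land exactly on the sample grid (rejected
otherwise, never silently rounded) so that interleaving is an exact
partition of the samples — this is what lets the interleaving identity
hold to machine precision. Pulse *onsets* at k/y generally fall between
samples; they are rounded with **second-order noise-shaped error
feedback** rather than per-pulse rounding. Plain rounding leaves a
deterministic timing-quantisation sideband at the F2−F1 bin of the
rectified-squared interleaved trains (about −112 dB re the primaries at
1 MHz / 2322 pps); shaping the rounding error with a second-order
high-pass loop keeps every onset within ~2 samples of its exact position
while pushing that energy far above the modulation band, leaving the bin
at about −137 dB.

## Distortion model

The nonlinearity is an ordered cascade of memoryless maps (reference:
half-wave rectification then squaring; arbitrary user maps allowed, with
g(0) = 0 required for the interleaving identity). Smoothing is a
30th-order low-pass IIR with a 300-Hz half-power point, realised as a
Butterworth cascade of second-order sections (the design family is not
fixed by the magnitude contract; Butterworth meets it: −3.01 ± 0.1 dB at
300 Hz, unity DC gain, passband ≤ 120 Hz flat within 0.5 dB, all poles
inside the unit circle), applied causally in one pass.

Spectra are one-sided FFTs scaled to peak-equivalent sinusoid amplitude
(a unit sinusoid reads 1.0; dB re 1 μA/μV as labelled), with Parseval
consistency checked to 1e-9 relative at every construction. Component
lookups require exact bin alignment and are rejected otherwise, so
leakage is never silently read as a component.

**DP decision rule.** The numerical floor for "no distortion product" is
120 dB below the larger primary, measured on the exact F2−F1 bin; a DP
counts as present when it rises at least 40 dB above that floor. The
8-panel outcome matrix (dyads/trains × superimposed/interleaved ×
with/without smoothing) reproduces: DP present for superimposed stimuli
with or without smoothing and for interleaved stimuli with smoothing;
absent (below floor) for interleaved stimuli without smoothing.

## Synthetic EEG

Each channel is a sum of steady-state sinusoids plus noise, generated on
the recorder's sampling grid with a constant stimulator/recorder
clock-rate ratio r (default ±50 ppm configurable, no jitter):

* artefact at F1 and F2 with phase 0 (sine convention) at every true
  epoch onset — zero group delay; amplitudes per channel, large
  ipsilaterally (10/8 μV defaults), small contralaterally (0.4/0.3 μV);
* NDR at F0 = F2−F1 with phase −2π·F0·τ + φ₀ (τ = 45 ms default,
  amplitude 10^(−14.1/20) ≈ 0.197 μV ≈ −14.1 dB re 1 μV), uniform across
  scalp channels and absent from the reference;
* white Gaussian noise (optional 1/f weighting). Defaults follow the
  measurement conditions: 300 one-second epochs, 262,144-Hz recorder
  (2¹⁸; the hardware figure "262,144 kHz" is read as Hz). Tests and demos
  pass 8192–16384-Hz recorder rates and 60–300 epochs so the whole suite
  runs in minutes; all analysis frequencies stay far below Nyquist either
  way, and the structure of the data is identical. With an 8192-Hz
  recorder, 150 epochs and noise SD 8 μV the averaged-epoch 12-bin noise
  floor lands near −35 dB re 1 μV (the generator is calibrated so that
  plausible choices reproduce floors in the −30 dB region reported for
  real recordings).

Onset transients, volume conduction, recording-system nonlinearity, and
pulse-shaped artefact waveforms are *not* modelled on this path (the
interleaved method needs none of them; pulse-shaped spike artefact exists
separately in the blanking-path generator). Passing tests therefore show
the measurement chain is correct under its stated assumptions, not that
real EEG meets those assumptions.

**Spatial model.** For tuning experiments, each stimulating electrode
excites an exponential profile exp(−|x−x_e|/λ) along the array
(λ = 3 mm default, 0.75-mm pitch so 6/12-electrode separations are
4.5/9 mm); the NDR amplitude is a_max (default −16.5 dB re 1 μV) times
the normalised overlap of the two profiles, which equals
e^(−d/λ)(1 + d/λ) in continuous space — monotone in separation, full at
zero. λ = 3 mm makes the 6-electrode separation drop ≈5 dB and the
12-electrode separation fall to the noise floor, the qualitative pattern
the method is designed to resolve.

## Analysis chain

1. **Montage** (raw-trace arithmetic before any spectral step): mean of
   the mastoid-region and occipital channels minus Cz by default;
   per-channel analyses use a single channel minus the reference.
2. **Epoching**: one epoch per trigger; incomplete trailing epochs are
   dropped and counted.
3. **Clock-ratio estimation and re-cut**: a straight line fitted to
   trigger index vs epoch number gives the effective
   stimulator/recorder ratio to ≪1 ppm (300 triggers, ±0.5-sample
   rounding); if residuals exceed 1.5 samples the code warns and falls
   back to the median inter-trigger interval. Epochs are then resampled
   onto the stimulator time base by linear interpolation at the exact
   fractional positions. Linear interpolation suffices because the
   analysis band sits 2 orders of magnitude below the recorder rate
   (worst-case amplitude error ~1e-4 at 43 Hz / 8192 Hz); at 50-ppm drift
   the corrected adjacent-bin leakage of a coherent 40-Hz component is
   ≈−134 dB versus ≈−54 dB uncorrected (>40 dB suppression). With
   r = 1 the re-cut is sample-exact.
4. **Averaging**: pointwise mean; incoherent noise power drops as 1/N.
5. **Extraction**: amplitude/phase from the exact bin (sine-convention
   phase, directly comparable to generator phases).
6. **F test**: target-bin power over the mean power of the 6 nearest
   valid bins on each side; bins holding the other stimulus components,
   their low-order harmonics, or mains (50 Hz) are skipped and the search
   extends outward. The 10.92 threshold is used as printed; empirically
   the null statistic follows F(2,24), whose exceedance probability at
   10.92 is ≈4e-4, comfortably below the stated 1 % level (the printed
   threshold is honoured rather than re-derived).
7. **Group delay**: phases at the F0 set are unwrapped by choosing, per
   inter-frequency step, the 2π multiple consistent with a delay in
   [0, 100] ms (covering peripheral-to-cortical latencies) with 0.5-rad
   noise slack; a least-squares line gives τ = −slope/2π. With 3-Hz
   steps the window is shorter than one cycle, so the choice is unique;
   were several delays plausible the result is flagged and all candidates
   reported. Fitted delays slightly outside the range are reported as-is
   (clamping would bias near-zero artefact delays). Two frequencies
   reduce to the exact two-point slope.
8. **Tuning curves**: same-electrode and F1-fixed families keyed by F2
   electrode, explicit gaps for missing conditions, values at/below the
   noise floor or non-significant flagged.

## Blanking path (EASSR)

Windows from 0.2 ms before to 1.4 ms after each pulse onset (anchored at
the leading edge of the first phase) are merged and replaced per raw
channel by the straight line joining the nearest intact samples;
everything outside is bit-identical. Pulse times derive from the nominal
rate mapped through the trigger-estimated clock ratio, so windows stay
centred under drift. The operation is idempotent and linear in the data.
A guard refuses the operation when under 10 % of samples would remain
intact, reporting the coverage — at 4644 pps the 1.6-ms window exceeds
the 0.215-ms period entirely (100 % coverage), which is exactly why the
blanking method cannot operate at interleaved-method rates, while at
500 pps 20 % of samples survive and a 40-Hz neural component is recovered
within 0.33 dB and 1.3° (60 epochs, 20 seeds). Whether interpolation runs
before or after montage derivation is unspecified in the measurement
description; it runs per raw channel, before montage.

## Problem sizes

Distortion panels: 1 s at 1 MHz (bin width 1 Hz). Synthetic experiments:
8192-Hz recorder, 150 one-second epochs, noise SD 8 μV (demo); tuning
uses 150 epochs per condition; blanking round trip uses a 16384-Hz
recorder (good spike sampling) and 60 epochs; null calibration uses
10,000 independent 1024-point noise spectra. These sizes were chosen so
the full suite and the acceptance script each run in well under a minute
while keeping every quantity's Monte-Carlo error far inside its decision
margin (e.g. group-delay σ ≈ 1.2 ms against a 45-ms target).

## Known limitations

* The NDR generator is phenomenological (steady-state sinusoid); it does
  not model the neural transduction that creates the distortion, only
  its spectral consequence. The distortion module demonstrates the
  mechanism on stimuli, not on simulated neurons.
* Clock drift is a constant ratio; oscillator wander or trigger jitter
  beyond ±1 sample triggers only a robust fallback, not a jitter model.
* Blanking interpolation is linear, as in the method it reproduces;
  spline or model-based interpolation is an extension point.
* The 10.92 F threshold is treated as a constant of the method; its
  derivation is not reproduced.
* Device electronics (capacitive smoothing inside a real implant, which
  leaves a small residual distortion product in real measurements) are
  out of scope; the simulations show the ideal-device behaviour.
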