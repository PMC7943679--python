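"""Stimulus construction: stepped analogue dyads and AM biphasic pulse trains.

Two stimulus families are supported, both built at a configurable simulation
rate (1 MHz by default):

* *Analogue dyads* — the sum (or exact time-division interleaving) of two
  sinusoids F1 and F2, optionally approximated as a stepped, 8-bit quantised
  waveform as produced by a clinical stimulator.
* *AM pulse trains* — charge-balanced symmetric biphasic pulse trains,
  sinusoidally amplitude modulated in linear current between a threshold (T)
  and a most-comfortable (MCL) level.  Two trains modulated at F1 and F2 can
  be interleaved so that each pulse of one train falls exactly mid-way
  between two pulses of the other, doubling the composite rate while keeping
  the pulses non-overlapping.

All durations must land on the sample grid (see
:func:`alfies.waveform.as_integer_samples`); pulse onsets are rounded to the
nearest sample while the modulator is always evaluated at the exact
(unrounded) onset time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .waveform import SampledWaveform, as_integer_samples

__all__ = [
    "DyadSpec",
    "PulseTrainSpec",
    "PulseTrain",
    "make_stepped_dyad",
    "make_biphasic_train",
    "apply_sinusoidal_am",
    "interleave_pulse_trains",
    "make_summed_modulator_train",
    "device_dyad_f0",
    "pulse_width",
    "inter_pulse_gap",
    "per_train_rate_for_f0",
    "quantize_midrise",
]

_DYAD_MODES = (
    "superimposed",
    "interleaved_same_electrode",
    "interleaved_different_electrodes",
)


def device_dyad_f0(steps_per_period: int = 72, step_duration: float = 126.26e-6) -> float:
    """Fundamental (difference) frequency of a stepped device dyad in Hz.

    One F0 period consists of ``steps_per_period`` steps of
    ``step_duration`` seconds, so F0 = 1 / (steps_per_period * step_duration).
    With the 72 x 126.26-μs device timing this is 110.0023 Hz.
    """
    if steps_per_period <= 0 or step_duration <= 0:
        raise ValueError("steps_per_period and step_duration must be positive")
    return 1.0 / (steps_per_period * step_duration)


def pulse_width(phase_duration: float, inter_phase_gap: float) -> float:
    """Total biphasic pulse width in seconds (two phases plus the gap)."""
    return 2.0 * phase_duration + inter_phase_gap


def inter_pulse_gap(composite_rate: float, width: float) -> float:
    """Gap between consecutive composite pulses: period minus pulse width."""
    gap = 1.0 / composite_rate - width
    if gap < 0:
        raise ValueError(
            f"pulses of width {width * 1e6:.1f} us overlap at {composite_rate} pps"
        )
    return gap


def per_train_rate_for_f0(f0: float, pulses_per_period: int = 54) -> float:
    """Per-train pulse rate giving an integer number of pulses per F0 period."""
    return f0 * pulses_per_period


@dataclass(frozen=True)
class DyadSpec:
    """Declarative description of a two-sinusoid (dyad) stimulus.

    ``f1``/``f2`` are the nominal component frequencies (Hz, ``f2 > f1``).
    When ``steps_per_period`` is given, the actual fundamental is pinned to
    ``1/(steps_per_period * step_duration)`` — the device-timing value — and
    f1/f2 are rescaled proportionally (e.g. nominal 220/330 Hz becomes
    2*F0/3*F0 with F0 = 110.0023 Hz).
    """

    f1: float
    f2: float
    step_duration: float
    amplitude: float = 1.0
    steps_per_period: int | None = None
    quantization_bits: int | None = None
    duration_periods: int = 33
    mode: str = "interleaved_same_electrode"
    f1_electrode: int | None = None
    f2_electrode: int | None = None

    def __post_init__(self) -> None:
        if not (self.f2 > self.f1 > 0):
            raise ValueError(f"need f2 > f1 > 0, got f1={self.f1}, f2={self.f2}")
        if self.step_duration <= 0:
            raise ValueError("step_duration must be positive")
        if self.duration_periods < 1:
            raise ValueError("duration_periods must be >= 1")
        if self.mode not in _DYAD_MODES:
            raise ValueError(f"unknown dyad mode {self.mode!r}")
        if self.steps_per_period is not None and self.steps_per_period < 2:
            raise ValueError("steps_per_period must be >= 2")
        if self.quantization_bits is not None and self.quantization_bits < 2:
            raise ValueError("quantization_bits must be >= 2")

    @property
    def f0(self) -> float:
        """Difference frequency F2 - F1 in Hz (device timing wins if given)."""
        if self.steps_per_period is not None:
            return device_dyad_f0(self.steps_per_period, self.step_duration)
        return self.f2 - self.f1

    @property
    def effective_f1(self) -> float:
        return self.f1 * self.f0 / (self.f2 - self.f1)

    @property
    def effective_f2(self) -> float:
        return self.f2 * self.f0 / (self.f2 - self.f1)

    @property
    def duration(self) -> float:
        """Total stimulus duration in seconds (an exact number of F0 periods)."""
        return self.duration_periods / self.f0


def quantize_midrise(values: np.ndarray, bits: int, full_scale: float) -> np.ndarray:
    """Uniform mid-rise quantiser over [-full_scale, +full_scale].

    Values beyond the representable range are rejected (quantisation
    overflow), matching stimulator behaviour where the requested current must
    fit the DAC range.
    """
    values = np.asarray(values, dtype=np.float64)
    if np.any(np.abs(values) > full_scale * (1 + 1e-12)):
        raise ValueError(
            f"quantization overflow: |value| exceeds full scale {full_scale}"
        )
    delta = 2.0 * full_scale / (2**bits)
    q = (np.floor(values / delta) + 0.5) * delta
    top = full_scale - delta / 2.0
    return np.clip(q, -top, top)


def make_stepped_dyad(spec: DyadSpec, sample_rate: float) -> SampledWaveform:
    """Piecewise-constant (stepped) realisation of a dyad.

    The amplitude is constant during each step of ``spec.step_duration``; in
    the interleaved modes the steps alternate strictly between the F1 and F2
    sinusoids (even steps carry F1).  Each step takes the value of its
    component sinusoid at the step onset.  With ``quantization_bits`` set,
    step amplitudes pass through a uniform mid-rise quantiser spanning
    [-amplitude, +amplitude].
    """
    samples_per_step = as_integer_samples(
        spec.step_duration, sample_rate, "step_duration"
    )
    n_steps_f = spec.duration / spec.step_duration
    n_steps = int(round(n_steps_f))
    if abs(n_steps_f - n_steps) > 1e-6:
        raise ValueError(
            "duration is not an integer number of steps; choose duration_periods "
            "and step_duration consistently"
        )
    t = np.arange(n_steps) * spec.step_duration
    a = spec.amplitude
    s1 = a * np.sin(2.0 * np.pi * spec.effective_f1 * t)
    s2 = a * np.sin(2.0 * np.pi * spec.effective_f2 * t)
    if spec.mode == "superimposed":
        step_values = s1 + s2
    else:
        even = np.arange(n_steps) % 2 == 0
        step_values = np.where(even, s1, s2)
    if spec.quantization_bits is not None:
        # Full scale is the per-component amplitude: a superimposed dyad can
        # exceed it and is rejected, as it would be by the stimulator DAC.
        step_values = quantize_midrise(step_values, spec.quantization_bits, a)
    samples = np.repeat(step_values, samples_per_step)
    return SampledWaveform(samples, sample_rate, "uA")


@dataclass(frozen=True)
class PulseTrainSpec:
    """Declarative description of one AM biphasic pulse train.

    All durations are in seconds and currents in μA.  ``per_train_rate`` is
    the pulse rate of this single train (symbol *y*); interleaving two trains
    doubles the composite rate.  The sinusoidal amplitude modulation runs in
    linear current between ``level_low`` (threshold T) and ``level_high``
    (MCL).
    """

    per_train_rate: float
    phase_duration: float = 25e-6
    inter_phase_gap: float = 8e-6
    polarity: str = "cathodic_first"
    mod_freq: float | None = None
    mod_depth: float = 1.0
    level_low: float = 0.0
    level_high: float = 1.0
    electrode: int | None = None
    duration: float = 1.0
    pulses_per_f0_period: int = 54

    def __post_init__(self) -> None:
        if self.per_train_rate <= 0:
            raise ValueError("per_train_rate must be positive")
        if self.phase_duration <= 0 or self.inter_phase_gap < 0:
            raise ValueError("phase_duration must be > 0 and inter_phase_gap >= 0")
        if self.polarity not in ("cathodic_first", "anodic_first"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        width = pulse_width(self.phase_duration, self.inter_phase_gap)
        if self.per_train_rate * width > 1.0 + 1e-12:
            raise ValueError(
                f"pulses of width {width * 1e6:.1f} us overlap within a "
                f"{self.per_train_rate}-pps train"
            )
        if not (self.level_high >= self.level_low >= 0):
            raise ValueError("need level_high >= level_low >= 0")
        if self.mod_freq is not None and self.mod_freq >= self.per_train_rate / 2:
            raise ValueError(
                f"mod_freq {self.mod_freq} Hz is not below half the pulse rate; "
                "the modulator would be undersampled by the pulses"
            )
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @property
    def width(self) -> float:
        return pulse_width(self.phase_duration, self.inter_phase_gap)


@dataclass
class PulseTrain:
    """A realised pulse train: waveform plus exact pulse bookkeeping.

    ``onset_times`` are the exact (unrounded) pulse onsets in seconds;
    ``onset_samples`` are the rounded sample indices where each pulse was
    placed.  ``rate`` is the pulse rate of this waveform (composite rate
    after interleaving).
    """

    waveform: SampledWaveform
    onset_samples: np.ndarray
    onset_times: np.ndarray
    pulse_samples: int
    rate: float

    @property
    def n_pulses(self) -> int:
        return int(self.onset_samples.size)

    @property
    def sample_rate(self) -> float:
        return self.waveform.sample_rate


def _noise_shaped_round(targets: np.ndarray) -> np.ndarray:
    """Round fractional sample positions with 2nd-order error feedback.

    Plain per-pulse rounding leaves a deterministic timing-quantisation
    sideband in the analysis baseband (around -112 dB re the primaries at
    1 MHz / 2322 pps); shaping the rounding error with a second-order
    high-pass loop pushes that energy far above the modulation band while
    keeping every onset within ~2 samples of its exact position.
    """
    out = np.empty(targets.size, dtype=np.int64)
    e1 = 0.0
    e2 = 0.0
    for i, tg in enumerate(targets):
        u = tg + 2.0 * e1 - e2
        s = round(u)
        e2 = e1
        e1 = u - s
        out[i] = s
    return out


def _pulse_shape(spec: PulseTrainSpec, sample_rate: float) -> np.ndarray:
    phase_n = as_integer_samples(spec.phase_duration, sample_rate, "phase_duration")
    gap_n = (
        0
        if spec.inter_phase_gap == 0
        else as_integer_samples(spec.inter_phase_gap, sample_rate, "inter_phase_gap")
    )
    lead = -1.0 if spec.polarity == "cathodic_first" else 1.0
    return np.concatenate(
        [
            np.full(phase_n, lead),
            np.zeros(gap_n),
            np.full(phase_n, -lead),
        ]
    )


def make_biphasic_train(spec: PulseTrainSpec, sample_rate: float) -> PulseTrain:
    """Unmodulated unit-amplitude biphasic pulse train.

    Pulse onsets sit at ``k / per_train_rate`` seconds (rounded to the
    nearest sample); every pulse is leading-phase / gap / opposite trailing
    phase and integrates to exactly zero (charge balance).
    """
    shape = _pulse_shape(spec, sample_rate)
    pulse_n = shape.size
    if sample_rate / spec.per_train_rate < pulse_n:
        raise ValueError("pulses overlap: rate too high for the pulse width")
    n_total = int(round(spec.duration * sample_rate))
    k = np.arange(int(np.ceil(spec.per_train_rate * spec.duration)) + 1)
    times = k / spec.per_train_rate
    onsets = _noise_shaped_round(times * sample_rate)
    keep = (onsets >= 0) & (onsets + pulse_n <= n_total)
    onsets, times = onsets[keep], times[keep]
    if onsets.size > 1 and int(np.diff(onsets).min()) < pulse_n:
        raise ValueError("pulses overlap: rate too high for the pulse width")
    samples = np.zeros(n_total)
    for s in onsets:
        samples[s : s + pulse_n] += shape
    return PulseTrain(
        waveform=SampledWaveform(samples, sample_rate, "uA"),
        onset_samples=onsets,
        onset_times=times,
        pulse_samples=pulse_n,
        rate=spec.per_train_rate,
    )


def _envelope(spec: PulseTrainSpec, mod_freq: float, t: np.ndarray) -> np.ndarray:
    lo, hi = spec.level_low, spec.level_high
    return lo + (hi - lo) * (1.0 + np.sin(2.0 * np.pi * mod_freq * t)) / 2.0


def apply_sinusoidal_am(train: PulseTrain, spec: PulseTrainSpec) -> PulseTrain:
    """Scale each pulse by the sinusoidal envelope at its exact onset time.

    The whole pulse (both phases) is scaled by one envelope value, so
    per-pulse charge balance is preserved.  The envelope runs in linear
    current from ``level_low`` to ``level_high``.
    """
    if spec.mod_freq is None:
        raise ValueError("spec.mod_freq is required for amplitude modulation")
    if spec.mod_freq >= train.rate / 2:
        raise ValueError(
            f"mod_freq {spec.mod_freq} Hz is not below half the train rate "
            f"({train.rate} pps); the modulator would be undersampled"
        )
    env = _envelope(spec, spec.mod_freq, train.onset_times)
    samples = train.waveform.samples.copy()
    for s, g in zip(train.onset_samples, env):
        samples[s : s + train.pulse_samples] *= g
    return replace(train, waveform=train.waveform.with_samples(samples))


def interleave_pulse_trains(a: PulseTrain, b: PulseTrain) -> PulseTrain:
    """Interleave two equal-rate trains, offsetting ``b`` by half a period.

    Each pulse of ``b`` falls exactly mid-way between two pulses of ``a``;
    the composite rate is twice the per-train rate and no sample receives
    current from both trains.  The output is extended if a shifted pulse
    would otherwise be cut, so the total pulse count is conserved.
    """
    if a.sample_rate != b.sample_rate:
        raise ValueError("sample rates differ")
    if abs(a.rate - b.rate) > 1e-9 * a.rate:
        raise ValueError("per-train rates differ")
    if a.pulse_samples != b.pulse_samples:
        raise ValueError("pulse widths differ")
    fs = a.sample_rate
    half_period = 1.0 / (2.0 * a.rate)
    offset = int(round(fs * half_period))
    if offset < a.pulse_samples:
        raise ValueError(
            "pulses from the two trains overlap: composite rate too high for "
            f"the {a.pulse_samples / fs * 1e6:.0f}-us pulse width"
        )
    b_onsets = b.onset_samples + offset
    n_out = max(
        len(a.waveform),
        int(a.onset_samples.max(initial=0)) + a.pulse_samples,
        int(b_onsets.max(initial=0)) + a.pulse_samples,
    )
    samples = np.zeros(n_out)
    samples[: len(a.waveform)] += a.waveform.samples
    # b's tail beyond n_out is all zeros (its last pulse fits by construction)
    b_end = min(n_out, offset + len(b.waveform))
    samples[offset:b_end] += b.waveform.samples[: b_end - offset]
    onsets = np.concatenate([a.onset_samples, b_onsets])
    times = np.concatenate([a.onset_times, b.onset_times + half_period])
    order = np.argsort(onsets)
    onsets, times = onsets[order], times[order]
    if np.any(np.diff(onsets) < a.pulse_samples):
        raise ValueError("pulses from the two trains overlap after offsetting")
    return PulseTrain(
        waveform=SampledWaveform(samples, fs, "uA"),
        onset_samples=onsets,
        onset_times=times,
        pulse_samples=a.pulse_samples,
        rate=2.0 * a.rate,
    )


def make_summed_modulator_train(
    composite_rate: float,
    f1: float,
    f2: float,
    spec: PulseTrainSpec,
    sample_rate: float,
) -> PulseTrain:
    """Single train at the composite rate, modulated by the mean of two
    sinusoidal envelopes (the superimposed-modulator control stimulus).

    Each pulse amplitude is ``[m1(t) + m2(t)] / 2`` where ``m1``/``m2`` are
    the F1- and F2-Hz envelopes between ``level_low`` and ``level_high``.
    """
    if composite_rate <= 2 * max(f1, f2):
        raise ValueError("composite_rate must exceed twice the highest modulator")
    base_spec = replace(spec, per_train_rate=composite_rate, mod_freq=None)
    base = make_biphasic_train(base_spec, sample_rate)
    env = 0.5 * (
        _envelope(spec, f1, base.onset_times) + _envelope(spec, f2, base.onset_times)
    )
    samples = base.waveform.samples.copy()
    for s, g in zip(base.onset_samples, env):
        samples[s : s + base.pulse_samples] *= g
    return replace(base, waveform=base.waveform.with_samples(samples))
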