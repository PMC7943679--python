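"""Instantaneous nonlinearities, pre-nonlinearity smoothing, and spectra.

The scientific core: an instantaneous (memoryless) nonlinearity *g* with
g(0) = 0 applied to a time-division interleaved stimulus satisfies, sample
by sample, ``g(x_int) = g(x1_masked) + g(x2_masked)`` — at any instant only
one component is non-zero.  Because the Fourier transform is linear, the
spectrum of the distorted composite is the sum of the two distorted
component spectra, so no energy can appear at combination frequencies such
as F2−F1 that depend on *both* components.  Smoothing the stimulus *before*
the nonlinearity mixes the components at every instant and re-introduces a
difference-frequency distortion product (DP); this is the signature the
neural distortion response relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import signal

from .waveform import SampledWaveform, interleave_segments, make_sinusoid, superimpose

__all__ = [
    "NonlinearitySpec",
    "rectify_square",
    "SmoothingSpec",
    "Spectrum",
    "apply_nonlinearity",
    "apply_smoothing",
    "compute_spectrum",
    "dp_amplitude",
    "verify_interleave_identity",
    "IdentityReport",
    "run_distortion_scenario",
    "ScenarioResult",
    "STIMULUS_KINDS",
]

_STAGE_MAP: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "half_wave_rectify": lambda x: np.maximum(x, 0.0),
    "square": lambda x: x * x,
    "identity": lambda x: x,
}


@dataclass(frozen=True)
class NonlinearitySpec:
    """Ordered cascade of memoryless pointwise maps.

    Stages are either names (``"half_wave_rectify"``, ``"square"``,
    ``"identity"``) or arbitrary callables operating elementwise on an
    array.  Every stage must be memoryless: each output sample may depend
    only on the same input sample.
    """

    stages: tuple = ("half_wave_rectify", "square")

    def __post_init__(self) -> None:
        for s in self.stages:
            if isinstance(s, str) and s not in _STAGE_MAP:
                raise ValueError(
                    f"unknown stage {s!r}; known: {sorted(_STAGE_MAP)} or a callable"
                )

    def __call__(self, x: np.ndarray) -> np.ndarray:
        y = np.asarray(x, dtype=np.float64)
        for s in self.stages:
            fn = _STAGE_MAP[s] if isinstance(s, str) else s
            y = np.asarray(fn(y), dtype=np.float64)
        if not np.all(np.isfinite(y)):
            raise ValueError("nonlinearity produced non-finite values")
        return y

    def preserves_zero(self, tol: float = 0.0) -> bool:
        """True if g(0) == 0, the condition the interleave identity needs."""
        return abs(float(self(np.zeros(1))[0])) <= tol


def rectify_square() -> NonlinearitySpec:
    """Half-wave rectification followed by squaring (the reference cascade)."""
    return NonlinearitySpec(("half_wave_rectify", "square"))


def apply_nonlinearity(x: SampledWaveform, g: NonlinearitySpec) -> SampledWaveform:
    """Apply the stage cascade pointwise; length and rate are unchanged."""
    return x.with_samples(g(x.samples))


@dataclass(frozen=True)
class SmoothingSpec:
    """Low-pass IIR smoothing applied before the nonlinearity.

    Realised as a Butterworth design of the given order with its −3.01-dB
    (half-power) point at ``half_power_freq``, applied causally in cascaded
    second-order sections.  The stated magnitude behaviour (−3.01 dB at the
    half-power frequency, unity DC gain, flat low-frequency passband) is the
    contract; the Butterworth family is a realisation choice.
    """

    filter_order: int = 30
    half_power_freq: float = 300.0

    def design(self, sample_rate: float) -> np.ndarray:
        """Design second-order sections; reject an unstable realisation."""
        if sample_rate <= 2 * self.half_power_freq:
            raise ValueError("sample_rate must be well above the half-power frequency")
        sos = signal.butter(
            self.filter_order, self.half_power_freq, fs=sample_rate, output="sos"
        )
        # poles of each biquad must be strictly inside the unit circle
        for section in sos:
            poles = np.roots(section[3:])
            if np.any(np.abs(poles) >= 1.0):
                raise ValueError(
                    "designed smoothing filter is unstable at this sample rate"
                )
        return sos

    def magnitude_db(self, freqs: Sequence[float], sample_rate: float) -> np.ndarray:
        sos = self.design(sample_rate)
        _, h = signal.sosfreqz(sos, worN=np.asarray(freqs, float), fs=sample_rate)
        return 20.0 * np.log10(np.abs(h))


def apply_smoothing(x: SampledWaveform, s: SmoothingSpec) -> SampledWaveform:
    """One-pass (causal) filtering of the waveform with the smoothing filter."""
    sos = s.design(x.sample_rate)
    return x.with_samples(signal.sosfilt(sos, x.samples))


@dataclass
class Spectrum:
    """One-sided amplitude/phase spectrum of a real signal.

    ``values[k]`` is scaled so that a unit-amplitude sinusoid aligned with
    bin *k* reads ``|values[k]| == 1`` (peak-equivalent amplitude).  Phase is
    the complex argument, i.e. the phase of an equivalent cosine.
    """

    frequencies: np.ndarray
    values: np.ndarray
    bin_width: float
    n_samples: int
    sample_rate: float
    reference: str = "uA"

    @property
    def amplitudes(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def phases(self) -> np.ndarray:
        return np.angle(self.values)

    def bin_index(self, freq: float, tol_bins: float = 1e-3) -> int:
        """Index of the bin exactly at ``freq``; reject misaligned lookups.

        Misaligned frequencies are rejected rather than rounded so that
        leakage is never silently read as a component amplitude.
        """
        k = freq / self.bin_width
        ki = int(round(k))
        if abs(k - ki) > tol_bins or not (0 <= ki < self.frequencies.size):
            raise ValueError(
                f"{freq} Hz is not aligned to the {self.bin_width}-Hz bin grid"
            )
        return ki

    def amplitude_at(self, freq: float) -> float:
        return float(np.abs(self.values[self.bin_index(freq)]))

    def phase_at(self, freq: float) -> float:
        return float(np.angle(self.values[self.bin_index(freq)]))


def compute_spectrum(x: SampledWaveform) -> Spectrum:
    """FFT-based one-sided spectrum with peak-equivalent amplitude scaling.

    Parseval consistency (time-domain energy vs spectral energy) is checked
    to 1e-9 relative at construction.
    """
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 samples")
    raw = np.fft.rfft(x.samples)
    values = raw / n
    values[1:] *= 2.0
    if n % 2 == 0:
        values[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / x.sample_rate)
    # Parseval check on the raw transform
    e_time = float(np.sum(x.samples**2))
    weights = np.full(raw.size, 2.0)
    weights[0] = 1.0
    if n % 2 == 0:
        weights[-1] = 1.0
    e_freq = float(np.sum(weights * np.abs(raw) ** 2) / n)
    scale = max(e_time, e_freq, 1e-300)
    if abs(e_time - e_freq) > 1e-9 * scale:
        raise AssertionError("Parseval consistency violated in compute_spectrum")
    return Spectrum(
        frequencies=freqs,
        values=values,
        bin_width=x.sample_rate / n,
        n_samples=n,
        sample_rate=x.sample_rate,
        reference=x.units,
    )


def dp_amplitude(s: Spectrum, f0: float) -> tuple[float, float]:
    """Amplitude and phase of the single bin at the difference frequency."""
    k = s.bin_index(f0)
    return float(np.abs(s.values[k])), float(np.angle(s.values[k]))


@dataclass
class IdentityReport:
    """Discrepancy between g(composite) and g(a)+g(b), absolute and relative."""

    max_time_discrepancy: float
    max_spectral_discrepancy: float
    time_peak: float
    spectral_peak: float

    @property
    def max_time_discrepancy_rel(self) -> float:
        return self.max_time_discrepancy / self.time_peak if self.time_peak else 0.0

    @property
    def max_spectral_discrepancy_rel(self) -> float:
        return (
            self.max_spectral_discrepancy / self.spectral_peak
            if self.spectral_peak
            else 0.0
        )


def verify_interleave_identity(
    a_masked: SampledWaveform,
    b_masked: SampledWaveform,
    composite: SampledWaveform,
    g: NonlinearitySpec,
) -> IdentityReport:
    """Measure how well ``g(composite) == g(a) + g(b)`` holds.

    ``a_masked``/``b_masked`` are the two masked components whose sum is the
    composite (each is zero wherever the other is active).  The identity
    requires ``g(0) == 0``; other nonlinearities are rejected with an
    explanation, since an inactive slot would then contribute a non-zero
    output.
    """
    if not g.preserves_zero():
        raise ValueError(
            "the interleave identity requires g(0) = 0: a component's inactive "
            "slots must contribute zero output"
        )
    ga = g(a_masked.samples)
    gb = g(b_masked.samples)
    gc = g(composite.samples)
    time_diff = float(np.max(np.abs(gc - (ga + gb))))
    time_peak = float(np.max(np.abs(gc)))
    sc = np.fft.rfft(gc)
    ss = np.fft.rfft(ga) + np.fft.rfft(gb)
    spec_diff = float(np.max(np.abs(sc - ss))) / len(composite)
    spec_peak = float(np.max(np.abs(sc))) / len(composite)
    return IdentityReport(time_diff, spec_diff, time_peak, spec_peak)


STIMULUS_KINDS = (
    "superimposed_dyad",
    "interleaved_dyad",
    "summed_modulator_train",
    "interleaved_am_trains",
)

# DP-absence floor: 120 dB below the larger primary, far beneath any
# double-precision leakage; a DP is "present" when it rises at least 40 dB
# above that floor.
DP_FLOOR_DB = -120.0
DP_PRESENT_MARGIN_DB = 40.0


@dataclass
class ScenarioResult:
    """Spectrum plus a difference-frequency distortion-product report."""

    kind: str
    smoothing_on: bool
    spectrum: Spectrum
    f0: float
    dp_amplitude: float
    dp_phase: float
    primary_amplitude: float
    dp_db_re_primary: float
    dp_present: bool


def _build_stimulus(
    kind: str,
    f1: float,
    f2: float,
    sample_rate: float,
    duration: float,
    per_train_rate: float,
    segment_duration: float,
) -> SampledWaveform:
    from . import stimgen  # local import to avoid a cycle at module load

    if kind == "superimposed_dyad":
        return superimpose(
            make_sinusoid(f1, 1.0, duration, sample_rate),
            make_sinusoid(f2, 1.0, duration, sample_rate),
        )
    if kind == "interleaved_dyad":
        return interleave_segments(
            make_sinusoid(f1, 1.0, duration, sample_rate),
            make_sinusoid(f2, 1.0, duration, sample_rate),
            segment_duration,
        )
    spec = stimgen.PulseTrainSpec(
        per_train_rate=per_train_rate,
        phase_duration=25e-6,
        inter_phase_gap=0.0,  # zero gap in the simulated trains
        level_low=0.0,
        level_high=1.0,
        duration=duration,
    )
    if kind == "summed_modulator_train":
        train = stimgen.make_summed_modulator_train(
            2 * per_train_rate, f1, f2, spec, sample_rate
        )
        return train.waveform
    if kind == "interleaved_am_trains":
        t1 = stimgen.apply_sinusoidal_am(
            stimgen.make_biphasic_train(spec, sample_rate),
            stimgen.PulseTrainSpec(
                **{**spec.__dict__, "mod_freq": f1}
            ),
        )
        t2 = stimgen.apply_sinusoidal_am(
            stimgen.make_biphasic_train(spec, sample_rate),
            stimgen.PulseTrainSpec(
                **{**spec.__dict__, "mod_freq": f2}
            ),
        )
        comp = stimgen.interleave_pulse_trains(t1, t2)
        # trim to the nominal duration so FFT bins stay on the 1/duration grid
        n = int(round(duration * sample_rate))
        return comp.waveform.with_samples(comp.waveform.samples[:n])
    raise ValueError(f"unknown stimulus kind {kind!r}; known: {STIMULUS_KINDS}")


def run_distortion_scenario(
    stimulus_kind: str,
    smoothing_on: bool,
    g: NonlinearitySpec | None = None,
    f1: float = 80.0,
    f2: float = 120.0,
    sample_rate: float = 1e6,
    duration: float = 1.0,
    per_train_rate: float = 2322.0,
    segment_duration: float = 200e-6,
    smoothing: SmoothingSpec | None = None,
    apply_g: bool = True,
) -> ScenarioResult:
    """Build a stimulus, optionally smooth it, distort it, and report the DP.

    Reproduces one panel of the simulation grid: stimulus family x
    {superimposed, interleaved} x {raw, nonlinearity, smoothing+nonlinearity}.
    The DP report compares the F2−F1 bin with the larger primary (F1/F2) bin
    and declares the DP present when it rises at least 40 dB above the
    −120-dB-re-primary numerical floor.
    """
    if g is None:
        g = rectify_square()
    if smoothing is None:
        smoothing = SmoothingSpec()
    x = _build_stimulus(
        stimulus_kind, f1, f2, sample_rate, duration, per_train_rate, segment_duration
    )
    if smoothing_on:
        x = apply_smoothing(x, smoothing)
    if apply_g:
        x = apply_nonlinearity(x, g)
    spec = compute_spectrum(x)
    f0 = f2 - f1
    dp_amp, dp_ph = dp_amplitude(spec, f0)
    primary = max(spec.amplitude_at(f1), spec.amplitude_at(f2))
    if primary <= 0:
        primary = float(np.max(spec.amplitudes[1:]))
    dp_db = 20.0 * np.log10(max(dp_amp, 1e-300) / primary)
    present = dp_db >= DP_FLOOR_DB + DP_PRESENT_MARGIN_DB
    return ScenarioResult(
        kind=stimulus_kind,
        smoothing_on=smoothing_on,
        spectrum=spec,
        f0=f0,
        dp_amplitude=dp_amp,
        dp_phase=dp_ph,
        primary_amplitude=primary,
        dp_db_re_primary=float(dp_db),
        dp_present=bool(present),
    )
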