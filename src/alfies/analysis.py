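"""The ALFIES measurement chain.

Epoching at the triggers, re-cutting to an exact integer number of stimulus
periods per epoch (correcting the stimulator-vs-recorder clock drift so the
primaries do not splatter across FFT bins), coherent averaging, exact-bin
component extraction, spectral F-ratio significance testing against the 12
flanking bins, group-delay estimation from the phase-vs-frequency slope,
and spatial tuning-curve assembly.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .distortion import Spectrum, compute_spectrum
from .synthrec import Recording
from .waveform import SampledWaveform

__all__ = [
    "Montage",
    "ComponentResult",
    "GroupDelayResult",
    "TuningCondition",
    "TuningCurve",
    "cut_epochs",
    "recut_to_integer_periods",
    "average_epochs",
    "extract_component",
    "f_test_component",
    "estimate_group_delay",
    "build_tuning_curve",
    "analyze_recording",
    "AnalysisResult",
    "F_RATIO_THRESHOLD",
]

logger = logging.getLogger(__name__)

# Critical F ratio for p < 0.01 (approximately 6 dB signal-to-noise ratio)
# when comparing the target-bin power with the mean of the 12 flanking bins.
F_RATIO_THRESHOLD = 10.92


@dataclass(frozen=True)
class Montage:
    """Channel combination used for analysis.

    The default mirrors common steady-state practice: the mean of the two
    mastoid-region channels and the occipital channel, referenced to Cz.
    Montage arithmetic is applied to the raw traces before any spectral
    step.
    """

    average: tuple = ("ipsi", "contra", "back")
    reference: str | None = "cz"

    def derive(self, rec: Recording) -> np.ndarray:
        trace = np.mean([rec.channel(c) for c in self.average], axis=0)
        if self.reference is not None:
            trace = trace - rec.channel(self.reference)
        return trace


def _resolve_trace(rec: Recording, montage: Montage | str | None) -> np.ndarray:
    """Derived single trace: a Montage, a channel name, or the sole channel."""
    if isinstance(montage, Montage):
        return montage.derive(rec)
    if isinstance(montage, str):
        return rec.channel(montage)
    if rec.n_channels == 1:
        return rec.data[0]
    return Montage().derive(rec)


@dataclass
class ComponentResult:
    """Amplitude, phase, and significance of one spectral component.

    ``phase`` uses the sine convention: a component ``A*sin(2πft + φ)``
    with the epoch starting at t = 0 is reported with phase φ.
    """

    frequency: float
    amplitude: float
    phase: float
    f_ratio: float
    significant: bool
    noise_floor: float  # amplitude-equivalent, same units as amplitude
    n_flanking: int = 12

    @property
    def amplitude_db(self) -> float:
        return 20.0 * np.log10(max(self.amplitude, 1e-300))

    @property
    def noise_floor_db(self) -> float:
        return 20.0 * np.log10(max(self.noise_floor, 1e-300))


@dataclass
class GroupDelayResult:
    """Group delay from the slope of unwrapped phase vs frequency."""

    frequencies: np.ndarray
    unwrapped_phases: np.ndarray
    delay_ms: float
    intercept: float
    residual: float
    ambiguous: bool = False
    candidate_delays_ms: tuple = ()


@dataclass
class TuningCondition:
    """One spatial-tuning measurement: which electrodes carried F1 and F2."""

    f1_electrode: int
    f2_electrode: int
    result: ComponentResult


@dataclass
class TuningCurve:
    """NDR amplitude vs F2 electrode, same- and different-electrode families.

    Amplitudes are in dB re 1 μV; entries are ``None`` where the condition
    was not measured.  ``flagged`` marks values at/below the noise floor or
    non-significant.
    """

    f2_electrodes: tuple
    same_electrode_db: tuple
    different_electrode_db: tuple
    noise_floor_db: tuple
    flagged_same: tuple
    flagged_different: tuple


def cut_epochs(
    rec: Recording,
    epoch_duration: float,
    montage: Montage | str | None = None,
) -> np.ndarray:
    """Cut the derived trace into one epoch per trigger.

    Epochs start at the trigger sample and span
    ``round(epoch_duration * sample_rate)`` samples; trailing epochs that
    run past the end of the recording are dropped (the count is logged).
    """
    if rec.trigger_indices.size == 0:
        raise ValueError("recording has no triggers; cannot epoch")
    trace = _resolve_trace(rec, montage)
    n_len = int(round(epoch_duration * rec.sample_rate))
    if n_len < 2:
        raise ValueError("epoch_duration too short for this sample rate")
    keep = rec.trigger_indices + n_len <= trace.size
    dropped = int(np.count_nonzero(~keep))
    if dropped:
        logger.info("cut_epochs: dropped %d incomplete trailing epoch(s)", dropped)
    starts = rec.trigger_indices[keep]
    if starts.size == 0:
        raise ValueError("no complete epochs fit in the recording")
    return trace[starts[:, None] + np.arange(n_len)[None, :]]


def estimate_clock_ratio(rec: Recording, epoch_duration: float) -> tuple[float, float]:
    """Stimulator/recorder clock ratio and sub-sample epoch start offset.

    A straight line is fitted to trigger index vs epoch number; the slope,
    divided by the nominal epoch length in samples, is the ratio.  If the
    trigger spacing jitters by more than one sample beyond the constant-
    drift model, a warning is issued and a robust median-spacing estimate
    is used instead.
    """
    trig = rec.trigger_indices
    if trig.size < 2:
        raise ValueError("need at least 2 triggers to estimate the clock ratio")
    k = np.arange(trig.size, dtype=np.float64)
    slope, intercept = np.polyfit(k, trig.astype(np.float64), 1)
    resid = trig - (intercept + slope * k)
    if np.max(np.abs(resid)) > 1.5:
        warnings.warn(
            "trigger spacing jitters beyond the constant-drift model; "
            "falling back to the median inter-trigger interval",
            stacklevel=2,
        )
        slope = float(np.median(np.diff(trig)))
        intercept = float(trig[0])
    nominal = epoch_duration * rec.sample_rate
    return slope / nominal, float(intercept)


def recut_to_integer_periods(
    rec: Recording,
    epoch_duration: float,
    montage: Montage | str | None = None,
) -> tuple[np.ndarray, float]:
    """Re-cut epochs so each holds an exact integer number of stimulus periods.

    The effective stimulator/recorder clock ratio is estimated from the
    triggers; each epoch is then resampled onto the stimulator's time base
    (epoch starts on the fitted trigger line, sample step scaled by the
    ratio), so that components that are periodic in stimulator time land on
    single FFT bins of the averaged epoch.  Returns ``(epochs, ratio)``.
    """
    ratio, intercept = estimate_clock_ratio(rec, epoch_duration)
    trace = _resolve_trace(rec, montage)
    n_len = int(round(epoch_duration * rec.sample_rate))
    step = epoch_duration * ratio * rec.sample_rate / n_len
    k = np.arange(rec.trigger_indices.size, dtype=np.float64)
    starts = intercept + k * (epoch_duration * ratio * rec.sample_rate)
    keep = starts + (n_len - 1) * step <= trace.size - 1
    dropped = int(np.count_nonzero(~keep))
    if dropped:
        logger.info(
            "recut_to_integer_periods: dropped %d incomplete epoch(s)", dropped
        )
    starts = starts[keep]
    if starts.size == 0:
        raise ValueError("no complete epochs fit in the recording")
    positions = starts[:, None] + np.arange(n_len)[None, :] * step
    grid = np.arange(trace.size, dtype=np.float64)
    epochs = np.interp(positions.ravel(), grid, trace).reshape(positions.shape)
    return epochs, ratio


def average_epochs(epochs: np.ndarray) -> np.ndarray:
    """Pointwise mean across epochs (coherent averaging)."""
    epochs = np.asarray(epochs, dtype=np.float64)
    if epochs.ndim != 2 or epochs.shape[0] == 0:
        raise ValueError("need a non-empty (n_epochs, n_samples) array")
    return epochs.mean(axis=0)


def _flanking_bins(
    spectrum: Spectrum,
    k: int,
    n_side: int,
    exclude_freqs: tuple,
) -> np.ndarray:
    """Indices of the n_side nearest valid bins on each side of bin k.

    Bins at excluded frequencies (primaries, their harmonics, mains) and the
    DC bin are skipped; the search extends outward until enough valid bins
    are found on each side.
    """
    excluded = set()
    for f in exclude_freqs:
        j = int(round(f / spectrum.bin_width))
        if abs(f / spectrum.bin_width - j) < 0.5 and 0 <= j < spectrum.values.size:
            excluded.add(j)
    out: list[int] = []
    for direction in (-1, +1):
        found = 0
        j = k
        while found < n_side:
            j += direction
            if j <= 0 or j >= spectrum.values.size:
                raise ValueError(
                    f"fewer than {n_side} valid flanking bins available "
                    f"{'below' if direction < 0 else 'above'} {spectrum.frequencies[k]} Hz"
                )
            if j in excluded:
                continue
            out.append(j)
            found += 1
    return np.asarray(sorted(out), dtype=np.int64)


def f_test_component(
    spectrum: Spectrum,
    f: float,
    n_side: int = 6,
    threshold: float = F_RATIO_THRESHOLD,
    exclude_freqs: tuple = (),
) -> tuple[float, bool, np.ndarray]:
    """Spectral F test: target-bin power vs the mean of 2*n_side flanking bins.

    Returns ``(f_ratio, significant, flank_indices)``; the component is
    deemed significant when the ratio exceeds ``threshold`` (10.92 for
    p < 0.01, approximately a 6-dB signal-to-noise ratio).
    """
    k = spectrum.bin_index(f)
    flanks = _flanking_bins(spectrum, k, n_side, exclude_freqs)
    p_target = float(np.abs(spectrum.values[k]) ** 2)
    p_noise = float(np.mean(np.abs(spectrum.values[flanks]) ** 2))
    if p_noise == 0.0:
        f_ratio = np.inf if p_target > 0 else 0.0
    else:
        f_ratio = p_target / p_noise
    return float(f_ratio), bool(f_ratio > threshold), flanks


def extract_component(
    avg_epoch: np.ndarray,
    sample_rate: float,
    f: float,
    n_side: int = 6,
    threshold: float = F_RATIO_THRESHOLD,
    exclude_freqs: tuple = (),
    units: str = "uV",
) -> ComponentResult:
    """Amplitude/phase of the exact bin at ``f`` plus F-ratio significance.

    The frequency must be bin-aligned (guaranteed after
    :func:`recut_to_integer_periods` for stimulus-locked components);
    misaligned frequencies are rejected.  Phase is reported in the sine
    convention so it is directly comparable with generator phases.
    """
    spectrum = compute_spectrum(SampledWaveform(avg_epoch, sample_rate, units))
    k = spectrum.bin_index(f)
    amplitude = float(np.abs(spectrum.values[k]))
    # FFT phase is cosine-referenced; shift by +π/2 to the sine convention.
    phase = float(np.angle(spectrum.values[k]) + np.pi / 2.0)
    phase = (phase + np.pi) % (2.0 * np.pi) - np.pi
    f_ratio, significant, flanks = f_test_component(
        spectrum, f, n_side, threshold, exclude_freqs
    )
    noise_floor = float(np.sqrt(np.mean(np.abs(spectrum.values[flanks]) ** 2)))
    return ComponentResult(
        frequency=f,
        amplitude=amplitude,
        phase=phase,
        f_ratio=f_ratio,
        significant=significant,
        noise_floor=noise_floor,
        n_flanking=2 * n_side,
    )


def _fit_line(freqs: np.ndarray, phases: np.ndarray) -> tuple[float, float, float]:
    slope, intercept = np.polyfit(freqs, phases, 1)
    resid = phases - (intercept + slope * freqs)
    return float(slope), float(intercept), float(np.sum(resid**2))


def estimate_group_delay(
    frequencies,
    phases,
    delay_range_ms: tuple = (0.0, 100.0),
    tol_rad: float = 0.5,
) -> GroupDelayResult:
    """Group delay from the phase-vs-frequency slope.

    Phases (sine convention, wrapped) are unwrapped by choosing, for each
    inter-frequency step, the 2π multiple that keeps the phase decrease
    consistent with a delay inside ``delay_range_ms`` (±``tol_rad`` slack
    for noise); a least-squares line through the unwrapped phases then gives
    ``delay = -slope / 2π``.  If several unwrapping choices yield plausible
    delays, the result is flagged ambiguous and all candidates reported.
    With exactly two frequencies the estimate equals the two-point slope.
    """
    freqs = np.asarray(frequencies, dtype=np.float64)
    phases = np.asarray(phases, dtype=np.float64)
    if freqs.size < 2:
        raise ValueError("need phases at >= 2 frequencies")
    order = np.argsort(freqs)
    freqs, phases = freqs[order], phases[order]
    tau_lo, tau_hi = (d / 1000.0 for d in delay_range_ms)
    if not tau_hi > tau_lo:
        raise ValueError("delay_range_ms must be increasing")

    diffs = np.diff(phases)
    step_candidates: list[list[float]] = []
    for df, d in zip(np.diff(freqs), diffs):
        lo = -2.0 * np.pi * df * tau_hi - tol_rad
        hi = -2.0 * np.pi * df * tau_lo + tol_rad
        ks = np.arange(np.ceil((lo - d) / (2 * np.pi)), np.floor((hi - d) / (2 * np.pi)) + 1)
        cands = [d + 2.0 * np.pi * k for k in ks]
        if not cands:
            # fall back to the candidate closest to the window
            k = round(((lo + hi) / 2 - d) / (2 * np.pi))
            cands = [d + 2.0 * np.pi * k]
        step_candidates.append(cands)

    fits = []
    for combo in itertools.product(*step_candidates):
        unwrapped = np.concatenate([[phases[0]], phases[0] + np.cumsum(combo)])
        slope, intercept, resid = _fit_line(freqs, unwrapped)
        delay_ms = -slope / (2.0 * np.pi) * 1000.0
        fits.append((resid, delay_ms, intercept, unwrapped))
    margin = 10.0  # ms of slack on the range for noisy near-boundary delays
    valid = [
        f
        for f in fits
        if delay_range_ms[0] - margin <= f[1] <= delay_range_ms[1] + margin
    ]
    if not valid:
        valid = fits
    valid.sort(key=lambda f: f[0])
    resid, delay_ms, intercept, unwrapped = valid[0]
    in_range = [
        f for f in valid if delay_range_ms[0] <= f[1] <= delay_range_ms[1]
    ]
    ambiguous = len(in_range) > 1
    return GroupDelayResult(
        frequencies=freqs,
        unwrapped_phases=unwrapped,
        delay_ms=float(delay_ms),
        intercept=float(intercept),
        residual=float(resid),
        ambiguous=ambiguous,
        candidate_delays_ms=tuple(round(f[1], 6) for f in valid[:4]),
    )


def build_tuning_curve(conditions) -> TuningCurve:
    """Assemble a spatial tuning curve from per-condition component results.

    Same-electrode conditions (F1 and F2 on the same electrode) and
    different-electrode conditions (F1 fixed, F2 moved) are keyed by the F2
    electrode; missing conditions leave explicit ``None`` gaps.  Amplitudes
    at/below the noise floor or non-significant are flagged.
    """
    same: dict[int, ComponentResult] = {}
    diff: dict[int, ComponentResult] = {}
    for c in conditions:
        target = same if c.f1_electrode == c.f2_electrode else diff
        target[c.f2_electrode] = c.result
    electrodes = tuple(sorted(set(same) | set(diff), reverse=True))

    def row(d: dict[int, ComponentResult]):
        amps, floors, flags = [], [], []
        for e in electrodes:
            r = d.get(e)
            if r is None:
                amps.append(None)
                floors.append(None)
                flags.append(False)
            else:
                amps.append(r.amplitude_db)
                floors.append(r.noise_floor_db)
                flags.append((not r.significant) or r.amplitude <= r.noise_floor)
        return tuple(amps), tuple(floors), tuple(flags)

    same_db, same_floor, same_flag = row(same)
    diff_db, diff_floor, diff_flag = row(diff)
    floors = tuple(
        s if s is not None else d for s, d in zip(same_floor, diff_floor)
    )
    return TuningCurve(
        f2_electrodes=electrodes,
        same_electrode_db=same_db,
        different_electrode_db=diff_db,
        noise_floor_db=floors,
        flagged_same=same_flag,
        flagged_different=diff_flag,
    )


@dataclass
class AnalysisResult:
    """Full single-recording analysis: components at F0, F1, F2."""

    components: dict
    n_epochs: int
    clock_ratio: float
    epoch_duration: float


def analyze_recording(
    rec: Recording,
    f0: float,
    f1: float,
    f2: float,
    epoch_duration: float = 1.0,
    montage: Montage | str | None = None,
    n_side: int = 6,
    threshold: float = F_RATIO_THRESHOLD,
    mains_freq: float | None = 50.0,
) -> AnalysisResult:
    """Run the whole chain: montage, recut epochs, average, extract F0/F1/F2.

    Flanking-bin selection for each component skips the bins occupied by the
    other stimulus components, their low-order harmonics, and the mains
    frequency.
    """
    epochs, ratio = recut_to_integer_periods(rec, epoch_duration, montage)
    avg = average_epochs(epochs)
    harmonics = [h * f for f in (f0, f1, f2) for h in (1, 2, 3)]
    if mains_freq is not None:
        harmonics.append(mains_freq)
    components = {}
    for f in (f0, f1, f2):
        exclude = tuple(h for h in harmonics if abs(h - f) > 1e-9)
        components[f] = extract_component(
            avg,
            rec.sample_rate,
            f,
            n_side=n_side,
            threshold=threshold,
            exclude_freqs=exclude,
        )
    return AnalysisResult(
        components=components,
        n_epochs=epochs.shape[0],
        clock_ratio=ratio,
        epoch_duration=epoch_duration,
    )
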