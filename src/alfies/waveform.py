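"""Uniformly sampled waveforms and exact time-division interleaving.

Stimuli and recordings are represented as plain float64 sample sequences
tagged with a sample rate and a units label (``"uA"`` for stimulus current,
``"uV"`` for scalp potentials).  Interleaving is *exact*: segment boundaries
must fall on sample boundaries, so the two components partition the sample
grid with no overlap and no gap.  This exactness is what makes the
interleaving identity (see :mod:`alfies.distortion`) hold to machine
precision rather than approximately.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "SampledWaveform",
    "as_integer_samples",
    "make_sinusoid",
    "superimpose",
    "interleave_segments",
    "interleave_masked_components",
]

# Tolerance, in samples, for treating a duration as an integer sample count.
_INTEGER_TOL = 1e-6


def as_integer_samples(duration: float, sample_rate: float, what: str = "duration") -> int:
    """Convert a duration to an exact integer sample count or raise.

    Durations that do not land on the sample grid are rejected rather than
    silently rounded, so that segment/pulse bookkeeping stays exact.
    """
    n = duration * sample_rate
    k = int(round(n))
    if k <= 0 or abs(n - k) > _INTEGER_TOL:
        raise ValueError(
            f"{what} of {duration} s spans {n} samples at {sample_rate} Hz; "
            "it must be a positive integer number of samples"
        )
    return k


@dataclass
class SampledWaveform:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    samples
        Amplitude sequence (μA for stimuli, μV for recordings).
    sample_rate
        Sampling rate in Hz.
    units
        Free-text units label carried through operations.
    """

    samples: np.ndarray
    sample_rate: float
    units: str = "uA"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return self.samples.size / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.samples.size) / self.sample_rate

    def with_samples(self, samples: np.ndarray) -> "SampledWaveform":
        """Return a copy of this waveform with different samples."""
        return replace(self, samples=np.asarray(samples, dtype=np.float64))


def _check_compatible(a: SampledWaveform, b: SampledWaveform) -> None:
    if a.sample_rate != b.sample_rate:
        raise ValueError(
            f"sample rates differ ({a.sample_rate} vs {b.sample_rate} Hz)"
        )
    if len(a) != len(b):
        raise ValueError(f"lengths differ ({len(a)} vs {len(b)} samples)")


def make_sinusoid(
    freq: float,
    amplitude: float,
    duration: float,
    sample_rate: float,
    units: str = "uA",
    phase: float = 0.0,
) -> SampledWaveform:
    """Zero-phase sine wave: ``amplitude * sin(2*pi*freq*t + phase)``.

    The frequency must lie strictly below the Nyquist rate and the duration
    must be positive; violations raise ``ValueError``.
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration} s")
    if freq < 0 or freq >= sample_rate / 2:
        raise ValueError(
            f"frequency {freq} Hz is not below the Nyquist rate "
            f"({sample_rate / 2} Hz); it would alias"
        )
    n = int(round(duration * sample_rate))
    k = np.arange(n)
    samples = amplitude * np.sin(2.0 * np.pi * freq * k / sample_rate + phase)
    return SampledWaveform(samples, sample_rate, units)


def superimpose(a: SampledWaveform, b: SampledWaveform) -> SampledWaveform:
    """Pointwise sum of two equally sampled waveforms."""
    _check_compatible(a, b)
    return a.with_samples(a.samples + b.samples)


def _segment_masks(
    n: int, segment_samples: int, first_component: str
) -> tuple[np.ndarray, np.ndarray]:
    seg_index = np.arange(n) // segment_samples
    even = seg_index % 2 == 0
    if first_component == "a":
        return even, ~even
    if first_component == "b":
        return ~even, even
    raise ValueError(f"first_component must be 'a' or 'b', got {first_component!r}")


def interleave_masked_components(
    a: SampledWaveform,
    b: SampledWaveform,
    segment_duration: float,
    first_component: str = "a",
) -> tuple[SampledWaveform, SampledWaveform]:
    """Return the two masked components of a segment-interleaved stimulus.

    Contiguous segments of ``segment_duration`` alternate between the two
    inputs; where a component is inactive it contributes exact zeros.  The
    sum of the two returned waveforms is the interleaved composite, and
    their supports are disjoint (partition property).
    """
    _check_compatible(a, b)
    seg = as_integer_samples(segment_duration, a.sample_rate, "segment_duration")
    mask_a, mask_b = _segment_masks(len(a), seg, first_component)
    return (
        a.with_samples(np.where(mask_a, a.samples, 0.0)),
        b.with_samples(np.where(mask_b, b.samples, 0.0)),
    )


def interleave_segments(
    a: SampledWaveform,
    b: SampledWaveform,
    segment_duration: float,
    first_component: str = "a",
) -> SampledWaveform:
    """Alternate contiguous segments of ``a`` and ``b``.

    Odd-numbered segments (the first, third, ...) are drawn from the
    component named by ``first_component``; at every sample exactly one
    component contributes.
    """
    a_masked, b_masked = interleave_masked_components(
        a, b, segment_duration, first_component
    )
    return a_masked.with_samples(a_masked.samples + b_masked.samples)
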