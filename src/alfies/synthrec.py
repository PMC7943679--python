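"""Synthetic multi-channel EEG with the structure the analysis assumes.

The generator emulates the measurement situation of an interleaved-
stimulation EEG experiment:

* stimulus-artefact sinusoids at F1 and F2 with *zero group delay* (phase 0
  at every true epoch onset), much larger on the recording electrode
  ipsilateral to the implant than contralaterally;
* a neural distortion response (NDR) at F0 = F2−F1 with configurable
  amplitude and group delay (≈45 ms for a thalamic/cortical source),
  channel-uniform in amplitude;
* white (optionally 1/f-weighted) Gaussian background noise;
* a constant stimulator-vs-recorder clock-rate ratio (drift), with epoch
  triggers rounded to recorder samples.

A simple spatial-overlap model maps the separation between the two
stimulating electrodes to an NDR amplitude, for tuning-curve experiments:
each electrode excites an exponential spatial profile ``exp(-|x-x_e|/λ)``
along the array and the NDR scales with the normalised overlap of the two
profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Recording",
    "SyntheticEEGSpec",
    "simulate_recording",
    "ndr_amplitude_from_overlap",
    "DEFAULT_ARTEFACT_AMPLITUDES",
]

# Per-channel (amplitude at F1, amplitude at F2) in μV.  The ipsilateral
# electrode sees a far larger stimulus artefact than the contralateral one;
# "back" stands for an occipital electrode (Iz) and "cz" is the reference.
DEFAULT_ARTEFACT_AMPLITUDES: dict[str, tuple[float, float]] = {
    "ipsi": (10.0, 8.0),
    "contra": (0.4, 0.3),
    "back": (1.0, 0.8),
    "cz": (0.0, 0.0),
}


@dataclass
class Recording:
    """Multi-channel sampled EEG plus epoch triggers.

    ``data`` is ``(n_channels, n_samples)`` in μV.  ``trigger_indices`` mark
    epoch onsets in recorder samples.  ``clock_ratio_true`` (stimulator
    clock / recorder clock) is generator metadata: the analysis never reads
    it, it estimates the ratio from the triggers.
    """

    data: np.ndarray
    channel_names: tuple
    sample_rate: float
    trigger_indices: np.ndarray
    nominal_epoch_duration: float | None = None
    clock_ratio_true: float | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        self.channel_names = tuple(self.channel_names)
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("one channel name per data row is required")
        self.trigger_indices = np.asarray(self.trigger_indices, dtype=np.int64)
        if self.trigger_indices.size and np.any(np.diff(self.trigger_indices) <= 0):
            raise ValueError("trigger indices must be strictly increasing")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.data[self.channel_names.index(name)]
        except ValueError:
            raise KeyError(
                f"no channel {name!r}; have {self.channel_names}"
            ) from None


@dataclass
class SyntheticEEGSpec:
    """Conditions of a synthetic steady-state EEG measurement.

    Defaults mirror a 40-Hz difference-frequency experiment: modulation
    frequencies F1 = 80 and F2 = 120 Hz, 300 one-second epochs, an NDR of
    −14.1 dB re 1 μV with a 45-ms group delay, and a 262,144-Hz recorder.
    Tests and demos typically pass a smaller ``recorder_rate`` and
    ``n_epochs``; the structure is unchanged.
    """

    f1: float = 80.0
    f2: float = 120.0
    epoch_duration: float = 1.0
    n_epochs: int = 300
    recorder_rate: float = 262144.0
    artefact_amplitudes: dict = field(
        default_factory=lambda: dict(DEFAULT_ARTEFACT_AMPLITUDES)
    )
    ndr_amplitude: float = 10 ** (-14.1 / 20.0)  # μV, ≈ -14.1 dB re 1 μV
    ndr_group_delay: float = 0.045  # s
    ndr_onset_phase: float = 0.0  # rad, sine convention at the epoch onset
    noise_sd: float = 50.0  # μV per recorder sample
    one_over_f_weight: float = 0.0
    clock_ratio: float = 1.0  # stimulator clock / recorder clock
    reference_channel: str = "cz"

    def __post_init__(self) -> None:
        if not (self.f2 > self.f1 > 0):
            raise ValueError("need f2 > f1 > 0")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")
        if not self.clock_ratio > 0:
            raise ValueError("clock_ratio must be positive")
        if self.ndr_amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitudes must be non-negative")
        for name, (a1, a2) in self.artefact_amplitudes.items():
            if a1 < 0 or a2 < 0:
                raise ValueError(f"negative artefact amplitude for channel {name!r}")
        if self.f2 >= self.recorder_rate / 2:
            raise ValueError("component frequencies must lie below recorder Nyquist")

    @property
    def f0(self) -> float:
        return self.f2 - self.f1


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f-amplitude-shaped Gaussian noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shaping = np.zeros_like(f)
    shaping[1:] = 1.0 / np.sqrt(f[1:])
    pink = np.fft.irfft(spec * shaping, n)
    sd = pink.std()
    return pink / sd if sd > 0 else pink


def simulate_recording(
    spec: SyntheticEEGSpec,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> Recording:
    """Generate a Recording with artefact, NDR, noise, and clock drift.

    Artefact components have phase 0 (sine convention) at every true epoch
    onset — zero group delay.  The NDR carries phase
    ``-2π·F0·ndr_group_delay + ndr_onset_phase`` at each onset.  Epoch
    onsets are spaced ``epoch_duration * clock_ratio`` recorder seconds
    apart; trigger indices are those onsets rounded to recorder samples.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    fs = spec.recorder_rate
    r = spec.clock_ratio
    total = spec.n_epochs * spec.epoch_duration * r
    n = int(round(total * fs)) + int(round(0.01 * fs)) + 1
    t = np.arange(n) / fs
    # stimulator time: events generated on the stimulator clock appear
    # slowed/sped by the ratio r on the recorder's axis
    tau = t / r
    onsets = np.arange(spec.n_epochs) * spec.epoch_duration * r
    triggers = np.round(onsets * fs).astype(np.int64)

    ndr_phase = -2.0 * np.pi * spec.f0 * spec.ndr_group_delay + spec.ndr_onset_phase
    ndr = spec.ndr_amplitude * np.sin(2.0 * np.pi * spec.f0 * tau + ndr_phase)

    names = tuple(spec.artefact_amplitudes)
    data = np.empty((len(names), n))
    s1 = np.sin(2.0 * np.pi * spec.f1 * tau)
    s2 = np.sin(2.0 * np.pi * spec.f2 * tau)
    for i, name in enumerate(names):
        a1, a2 = spec.artefact_amplitudes[name]
        ch = a1 * s1 + a2 * s2
        if name != spec.reference_channel:
            ch = ch + ndr
        if spec.noise_sd > 0:
            white = rng.standard_normal(n)
            if spec.one_over_f_weight > 0:
                noise = (
                    (1.0 - spec.one_over_f_weight) * white
                    + spec.one_over_f_weight * _pink_noise(rng, n)
                )
            else:
                noise = white
            ch = ch + spec.noise_sd * noise
        data[i] = ch
    return Recording(
        data=data,
        channel_names=names,
        sample_rate=fs,
        trigger_indices=triggers,
        nominal_epoch_duration=spec.epoch_duration,
        clock_ratio_true=r,
    )


def ndr_amplitude_from_overlap(
    e_f1: int,
    e_f2: int,
    lam: float = 3.0,
    pitch: float = 0.75,
    a_max: float = 10 ** (-16.5 / 20.0),
    n_electrodes: int = 22,
    grid_step: float | None = None,
) -> float:
    """NDR amplitude from the overlap of two exponential excitation profiles.

    Each stimulating electrode excites ``exp(-|x - x_e| / lam)`` along the
    array (positions ``x_e = (e - 1) * pitch`` mm); the returned amplitude is
    ``a_max`` times the normalised inner product of the two profiles sampled
    on a fine grid spanning the array.  It equals ``a_max`` for the same
    electrode and decreases monotonically with separation.

    Defaults: λ = 3 mm, 0.75-mm pitch (so separations of 6 and 12 electrodes
    are 4.5 and 9 mm), ``a_max`` ≈ −16.5 dB re 1 μV.
    """
    if lam <= 0 or pitch <= 0:
        raise ValueError("lam and pitch must be positive")
    x1 = (e_f1 - 1) * pitch
    x2 = (e_f2 - 1) * pitch
    lo = min(0.0, x1, x2) - 6.0 * lam
    hi = max((n_electrodes - 1) * pitch, x1, x2) + 6.0 * lam
    step = grid_step if grid_step is not None else lam / 200.0
    x = np.arange(lo, hi + step, step)
    p1 = np.exp(-np.abs(x - x1) / lam)
    p2 = np.exp(-np.abs(x - x2) / lam)
    overlap = np.dot(p1, p2) / np.sqrt(np.dot(p1, p1) * np.dot(p2, p2))
    return float(a_max * overlap)
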