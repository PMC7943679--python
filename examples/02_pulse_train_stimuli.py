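"""Constructing interleaved amplitude-modulated biphasic pulse trains.

Two 2322-pps trains of 25-μs/phase, 8-μs-gap biphasic pulses are
amplitude-modulated at 80 and 120 Hz and interleaved so every pulse of one
train falls mid-way between two pulses of the other.
"""

import numpy as np

from alfies import (
    PulseTrainSpec,
    apply_sinusoidal_am,
    device_dyad_f0,
    inter_pulse_gap,
    interleave_pulse_trains,
    make_biphasic_train,
    per_train_rate_for_f0,
    pulse_width,
)

fs = 1e6  # 1-MHz simulation grid

spec = PulseTrainSpec(per_train_rate=2322.0, duration=1.0,
                      level_low=0.0, level_high=100.0)
width_us = pulse_width(spec.phase_duration, spec.inter_phase_gap) * 1e6
print(f"pulse width: {width_us:.0f} us (25 + 8 + 25)")

t1 = apply_sinusoidal_am(
    make_biphasic_train(spec, fs),
    PulseTrainSpec(**{**spec.__dict__, "mod_freq": 80.0}),
)
t2 = apply_sinusoidal_am(
    make_biphasic_train(spec, fs),
    PulseTrainSpec(**{**spec.__dict__, "mod_freq": 120.0}),
)
comp = interleave_pulse_trains(t1, t2)
print(f"per-train rate: {t1.rate:.0f} pps -> composite: {comp.rate:.0f} pps")
print(f"pulses: {t1.n_pulses} + {t2.n_pulses} = {comp.n_pulses}")
print(f"inter-pulse gap: {inter_pulse_gap(comp.rate, width_us * 1e-6) * 1e6:.0f} us")
print(f"charge balance: max |pulse integral| = "
      f"{max(abs(np.sum(comp.waveform.samples[s:s + comp.pulse_samples])) for s in comp.onset_samples):g} uA*sample")

print(f"\nper-train rates for 54 pulses per F0 period: "
      f"{[per_train_rate_for_f0(f, 54) for f in (37.0, 40.0, 43.0)]} pps")
print(f"stepped device dyad fundamental (72 x 126.26-us steps): "
      f"{device_dyad_f0():.4f} Hz")
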