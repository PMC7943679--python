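"""Spatial tuning: NDR amplitude vs separation of the stimulating electrodes.

The two modulated trains are presented either on the same electrode
(moving together along the array) or with F1 fixed apically (electrode 20)
while F2 moves basally (19, 14, 8 = separations of 1, 6, 12 electrodes,
about 0.75, 4.5, and 9 mm). The NDR requires a common neural population
driven by both trains, so its amplitude follows the overlap of the two
excitation profiles.
"""

from alfies import run_tuning_experiment

result = run_tuning_experiment(seed=0)
curve = result["curve"]

print("F2 electrode :", curve.f2_electrodes)
print("same electrode (dB re 1 uV):",
      ["-" if v is None else f"{v:.1f}" for v in curve.same_electrode_db])
print("F1 fixed at e20 (dB re 1 uV):",
      ["-" if v is None else f"{v:.1f}" for v in curve.different_electrode_db])
print("noise floor (dB re 1 uV):",
      ["-" if v is None else f"{v:.1f}" for v in curve.noise_floor_db])
print("at/below floor:", curve.flagged_different)

print(
    "\nSame-electrode amplitudes stay flat (~ -16.5 dB re 1 uV) wherever the\n"
    "pair is placed; with F1 fixed apically the NDR drops as F2 moves away\n"
    "and falls into the noise floor at a 12-electrode (9-mm) separation."
)
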