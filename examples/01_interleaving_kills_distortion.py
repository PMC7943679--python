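"""Why interleaving suppresses device distortion at the difference frequency.

Two sinusoids (80 and 120 Hz) are passed through an extreme instantaneous
nonlinearity (half-wave rectification + squaring), either superimposed or
interleaved in 200-μs segments, with and without a 30th-order 300-Hz
low-pass smoothing applied *before* the nonlinearity.
"""

from alfies import run_distortion_scenario

for kind in ("superimposed_dyad", "interleaved_dyad"):
    for smoothing in (False, True):
        r = run_distortion_scenario(kind, smoothing, duration=1.0)
        print(
            f"{kind:18s} smoothing={'on ' if smoothing else 'off'}  "
            f"DP at {r.f0:.0f} Hz: {r.dp_db_re_primary:8.1f} dB re primary  "
            f"-> {'PRESENT' if r.dp_present else 'absent'}"
        )

print(
    "\nThe difference-frequency distortion product (DP) vanishes for the\n"
    "interleaved stimulus (numerical floor, < -120 dB) because at any instant\n"
    "only one component is non-zero, so a memoryless nonlinearity cannot mix\n"
    "them. Smoothing before the nonlinearity re-mixes the components and the\n"
    "DP reappears - the signature of a response generated after neural\n"
    "integration rather than by the stimulating device."
)
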