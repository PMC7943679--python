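"""End-to-end synthetic experiment: detect the neural distortion response.

Three recordings (difference frequencies 37, 40, 43 Hz) are simulated with
a 45-ms-delay neural distortion response (NDR), zero-delay stimulus
artefacts, clock drift, and noise, then run through the full chain:
drift-corrected epoching, averaging, exact-bin extraction, F-test, and
group-delay estimation.
"""

import json

from alfies import run_end_to_end_demo

result = run_end_to_end_demo(seed=0)
report = result["report"]
print(json.dumps(report, indent=1))

print(
    f"\nThe NDR group delay ({report['ndr_group_delay_ms']} ms) recovers the"
    f"\nencoded 45 ms - a thalamic/cortical latency - while the stimulus"
    f"\nartefact at F1 shows ~0 ms delay ({report['artefact_group_delay_ms']} ms),"
    f"\nthe signature of a non-neural component. Per-channel amplitudes show"
    f"\nthe artefact is far larger ipsilaterally while the NDR is uniform"
    f"\nacross recording sites."
)
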