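"""High-level reproducible scenarios tying the modules together.

* :func:`run_figure_scenarios` — the 12-panel simulation grid (2 stimulus
  families × {superimposed, interleaved} × {raw, nonlinearity,
  smoothing+nonlinearity}) with a distortion-product presence table.
* :func:`run_end_to_end_demo` — synthetic 37/40/43-Hz experiment: generate
  three recordings, analyse each, report component amplitudes and
  significance, the NDR group delay, the artefact group delay, and the
  per-channel amplitude breakdown.
* :func:`run_tuning_experiment` — same-vs-different stimulating electrode
  conditions through the spatial-overlap model, assembled into a tuning
  curve.
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path

import numpy as np

from . import io as alfies_io
from .analysis import (
    Montage,
    TuningCondition,
    analyze_recording,
    build_tuning_curve,
    estimate_group_delay,
    extract_component,
    recut_to_integer_periods,
    average_epochs,
)
from .distortion import STIMULUS_KINDS, ScenarioResult, run_distortion_scenario
from .synthrec import SyntheticEEGSpec, ndr_amplitude_from_overlap, simulate_recording

__all__ = [
    "run_figure_scenarios",
    "run_end_to_end_demo",
    "run_tuning_experiment",
    "DEMO_RECORDER_RATE",
    "DEMO_N_EPOCHS",
    "DEMO_NOISE_SD",
]

# Demo problem sizes: an 8192-Hz recorder and 150 one-second epochs keep a
# full three-frequency experiment around 10^7 samples while leaving every
# analysis frequency far below Nyquist.
DEMO_RECORDER_RATE = 8192.0
DEMO_N_EPOCHS = 150
DEMO_NOISE_SD = 8.0


def run_figure_scenarios(
    sample_rate: float = 1e6,
    duration: float = 1.0,
    outdir=None,
) -> tuple[dict, list]:
    """Run the 12 simulation panels and build the DP presence table.

    Returns ``(panels, table)`` where ``panels`` maps panel names to
    :class:`~alfies.distortion.ScenarioResult` and ``table`` is a list of
    row dicts (family, arrangement, processing, dp_present, dp_db).
    With ``outdir`` set, per-panel spectra are written as CSV along with
    the table and a JSON report.
    """
    panels: dict[str, ScenarioResult] = {}
    table: list[dict] = []
    grid = [
        ("dyad", "superimposed", "superimposed_dyad"),
        ("dyad", "interleaved", "interleaved_dyad"),
        ("train", "superimposed", "summed_modulator_train"),
        ("train", "interleaved", "interleaved_am_trains"),
    ]
    for family, arrangement, kind in grid:
        for processing, smoothing_on, apply_g in (
            ("raw", False, False),
            ("nonlinearity", False, True),
            ("smoothing+nonlinearity", True, True),
        ):
            name = f"{family}_{arrangement}_{processing}"
            res = run_distortion_scenario(
                kind,
                smoothing_on,
                sample_rate=sample_rate,
                duration=duration,
                apply_g=apply_g,
            )
            panels[name] = res
            table.append(
                {
                    "family": family,
                    "arrangement": arrangement,
                    "processing": processing,
                    "dp_present": res.dp_present if apply_g else False,
                    "dp_db_re_primary": round(res.dp_db_re_primary, 2),
                }
            )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, res in panels.items():
            alfies_io.write_spectrum_csv(res.spectrum, outdir / f"{name}.csv")
        (outdir / "dp_table.json").write_text(json.dumps(table, indent=1))
    return panels, table


def _demo_spec(f0: float, **overrides) -> SyntheticEEGSpec:
    kwargs = dict(
        f1=2.0 * f0,
        f2=3.0 * f0,
        recorder_rate=DEMO_RECORDER_RATE,
        n_epochs=DEMO_N_EPOCHS,
        noise_sd=DEMO_NOISE_SD,
    )
    kwargs.update(overrides)
    return SyntheticEEGSpec(**kwargs)


def run_end_to_end_demo(
    seed: int = 0,
    f0_list=(37.0, 40.0, 43.0),
    outdir=None,
    **spec_overrides,
) -> dict:
    """Synthetic multi-frequency experiment mirroring the full workflow.

    For each difference frequency F0, a recording is generated (NDR with a
    45-ms group delay, zero-delay artefact, per-channel artefact asymmetry)
    and analysed through the full chain.  The report contains per-F0
    component results, the NDR and artefact group delays, and a
    per-channel amplitude breakdown at the middle F0.
    """
    rng = np.random.default_rng(seed)
    montage = Montage()
    per_f0 = {}
    ndr_phases, artefact_phases = [], []
    for f0 in f0_list:
        spec = _demo_spec(f0, **spec_overrides)
        rec = simulate_recording(spec, rng=rng)
        res = analyze_recording(
            rec, f0=f0, f1=spec.f1, f2=spec.f2, montage=montage,
            epoch_duration=spec.epoch_duration,
        )
        per_f0[f0] = {"spec": spec, "recording": rec, "analysis": res}
        ndr_phases.append(res.components[f0].phase)
        artefact_phases.append(res.components[spec.f1].phase)
    ndr_delay = estimate_group_delay(f0_list, ndr_phases)
    f1_list = [2.0 * f0 for f0 in f0_list]
    artefact_delay = estimate_group_delay(f1_list, artefact_phases)

    # per-channel breakdown at the middle frequency: artefact asymmetric
    # across recording electrodes, NDR roughly uniform
    mid = f0_list[len(f0_list) // 2]
    mid_rec = per_f0[mid]["recording"]
    mid_spec = per_f0[mid]["spec"]
    per_channel = {}
    for ch in mid_rec.channel_names:
        if ch == mid_spec.reference_channel:
            continue
        epochs, _ = recut_to_integer_periods(
            mid_rec, mid_spec.epoch_duration, montage=ch
        )
        avg = average_epochs(epochs)
        per_channel[ch] = {
            "ndr_db": extract_component(avg, mid_rec.sample_rate, mid).amplitude_db,
            "f1_db": extract_component(
                avg, mid_rec.sample_rate, mid_spec.f1
            ).amplitude_db,
        }

    report = {
        "f0_list_hz": list(f0_list),
        "ndr": {
            str(f0): {
                "amplitude_db_re_1uV": round(
                    per_f0[f0]["analysis"].components[f0].amplitude_db, 2
                ),
                "f_ratio": round(per_f0[f0]["analysis"].components[f0].f_ratio, 2),
                "significant": per_f0[f0]["analysis"].components[f0].significant,
                "noise_floor_db_re_1uV": round(
                    per_f0[f0]["analysis"].components[f0].noise_floor_db, 2
                ),
            }
            for f0 in f0_list
        },
        "ndr_group_delay_ms": round(ndr_delay.delay_ms, 2),
        "artefact_group_delay_ms": round(artefact_delay.delay_ms, 2),
        "per_channel_mid_f0": {
            ch: {k: round(v, 2) for k, v in d.items()}
            for ch, d in per_channel.items()
        },
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "end_to_end_report.json").write_text(json.dumps(report, indent=1))
    return {
        "report": report,
        "ndr_delay": ndr_delay,
        "artefact_delay": artefact_delay,
        "per_f0": per_f0,
    }


def run_tuning_experiment(
    seed: int = 0,
    f0: float = 43.0,
    apical_electrode: int = 20,
    f2_electrodes=(20, 19, 14, 8),
    lam_mm: float = 3.0,
    pitch_mm: float = 0.75,
    n_epochs: int = 150,
    outdir=None,
) -> dict:
    """Same- vs different-electrode conditions through the overlap model.

    Same-electrode conditions put both modulated trains on each F2
    electrode (full overlap: constant amplitude); different-electrode
    conditions keep F1 on the apical electrode while F2 moves basally, so
    the NDR follows the overlap of the two excitation profiles and falls
    into the noise floor at large separations.
    """
    rng = np.random.default_rng(seed)
    montage = Montage()
    conditions = []
    for e2 in f2_electrodes:
        e1_list = [e2] if e2 == apical_electrode else [e2, apical_electrode]
        for e1 in e1_list:
            amp = ndr_amplitude_from_overlap(e1, e2, lam=lam_mm, pitch=pitch_mm)
            spec = _demo_spec(f0, ndr_amplitude=amp, n_epochs=n_epochs)
            rec = simulate_recording(spec, rng=rng)
            res = analyze_recording(
                rec, f0=f0, f1=spec.f1, f2=spec.f2, montage=montage,
                epoch_duration=spec.epoch_duration,
            )
            conditions.append(
                TuningCondition(
                    f1_electrode=e1, f2_electrode=e2, result=res.components[f0]
                )
            )
    curve = build_tuning_curve(conditions)
    report = {
        "f2_electrodes": list(curve.f2_electrodes),
        "same_electrode_db": [
            None if v is None else round(v, 2) for v in curve.same_electrode_db
        ],
        "different_electrode_db": [
            None if v is None else round(v, 2) for v in curve.different_electrode_db
        ],
        "noise_floor_db": [
            None if v is None else round(v, 2) for v in curve.noise_floor_db
        ],
        "flagged_different": list(curve.flagged_different),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "tuning_report.json").write_text(json.dumps(report, indent=1))
    return {"curve": curve, "report": report, "conditions": conditions}
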