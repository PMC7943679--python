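"""Plain-text input/output for waveforms, recordings, and results.

Waveforms go to two-column CSV (time_s, amplitude).  Recordings go to a
multi-column CSV plus a JSON sidecar holding the sample rate, channel
names, trigger indices, and clock metadata — a deliberately simple,
text-only container.  An adapter from an ``mne`` Raw object covers reading
standard EEG containers (EDF/BDF via ``mne.io.read_raw_*``) without this
package growing its own binary parsers.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .synthrec import Recording
from .waveform import SampledWaveform

__all__ = [
    "write_waveform_csv",
    "write_recording",
    "read_recording",
    "write_spectrum_csv",
    "recording_from_mne",
]


def write_waveform_csv(x: SampledWaveform, path) -> None:
    """Two-column CSV: time_s, amplitude (units in the header)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", f"amplitude_{x.units}"])
        for t, v in zip(x.times, x.samples):
            w.writerow([f"{t:.9f}", f"{v:.9g}"])


def write_recording(rec: Recording, path) -> None:
    """CSV of channels plus a ``.json`` sidecar with all metadata."""
    path = Path(path)
    header = ",".join(rec.channel_names)
    np.savetxt(path, rec.data.T, delimiter=",", header=header, comments="", fmt="%.9g")
    sidecar = {
        "sample_rate_hz": rec.sample_rate,
        "channel_names": list(rec.channel_names),
        "trigger_indices": rec.trigger_indices.tolist(),
        "nominal_epoch_duration_s": rec.nominal_epoch_duration,
        "clock_ratio_true": rec.clock_ratio_true,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_recording(path) -> Recording:
    """Read a recording written by :func:`write_recording`."""
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2).T
    return Recording(
        data=data,
        channel_names=tuple(meta["channel_names"]),
        sample_rate=float(meta["sample_rate_hz"]),
        trigger_indices=np.asarray(meta["trigger_indices"], dtype=np.int64),
        nominal_epoch_duration=meta.get("nominal_epoch_duration_s"),
        clock_ratio_true=meta.get("clock_ratio_true"),
    )


def write_spectrum_csv(
    spectrum, path, reference_db: float = 1.0, max_frequency: float | None = 2000.0
) -> None:
    """CSV of (frequency_hz, amplitude_db, phase_deg) for one spectrum.

    By default only bins up to 2 kHz are written — the band the analyses
    read — which keeps files small at MHz simulation rates; pass
    ``max_frequency=None`` for the full one-sided spectrum.
    """
    path = Path(path)
    if max_frequency is not None:
        keep = spectrum.frequencies <= max_frequency
        spectrum = type(spectrum)(
            frequencies=spectrum.frequencies[keep],
            values=spectrum.values[keep],
            bin_width=spectrum.bin_width,
            n_samples=spectrum.n_samples,
            sample_rate=spectrum.sample_rate,
            reference=spectrum.reference,
        )
    amps = spectrum.amplitudes
    with np.errstate(divide="ignore"):
        amps_db = 20.0 * np.log10(np.maximum(amps, 1e-300) / reference_db)
    phase_deg = np.degrees(spectrum.phases)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frequency_hz", "amplitude_db", "phase_deg"])
        for f, a, p in zip(spectrum.frequencies, amps_db, phase_deg):
            w.writerow([f"{f:.6f}", f"{a:.3f}", f"{p:.3f}"])


def recording_from_mne(
    raw,
    trigger_indices,
    channel_map: dict | None = None,
    nominal_epoch_duration: float | None = None,
) -> Recording:
    """Build a Recording from an ``mne.io.Raw`` object.

    ``channel_map`` renames raw channel names to analysis names (e.g.
    ``{"P9": "ipsi", "P10": "contra", "Iz": "back", "Cz": "cz"}``); by
    default all channels are taken verbatim.  Data are converted from
    MNE's volts to μV.  Trigger sample indices are passed explicitly
    (e.g. from ``mne.find_events``).
    """
    if channel_map is None:
        picks = list(raw.ch_names)
        names = tuple(picks)
    else:
        picks = list(channel_map)
        names = tuple(channel_map[c] for c in picks)
    data = raw.get_data(picks=picks) * 1e6
    return Recording(
        data=data,
        channel_names=names,
        sample_rate=float(raw.info["sfreq"]),
        trigger_indices=np.asarray(trigger_indices, dtype=np.int64),
        nominal_epoch_duration=nominal_epoch_duration,
    )
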