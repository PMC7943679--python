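"""Declarative scenario configuration (JSON or YAML).

A single document describes a run: the synthetic-recording block, the
analysis block, and the seed.  Keys carry explicit units in their names
(``epoch_duration_s``, ``f1_hz``) to prevent unit drift; unknown keys are
rejected.  Every CLI run writes the resolved configuration beside its
outputs so the run is reproducible from that file plus the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .analysis import F_RATIO_THRESHOLD, Montage
from .synthrec import DEFAULT_ARTEFACT_AMPLITUDES, SyntheticEEGSpec

__all__ = ["ScenarioConfig", "load_config", "dump_resolved_config"]

_RECORDING_KEYS = {
    "f1_hz": "f1",
    "f2_hz": "f2",
    "epoch_duration_s": "epoch_duration",
    "n_epochs": "n_epochs",
    "recorder_rate_hz": "recorder_rate",
    "artefact_amplitudes_uv": "artefact_amplitudes",
    "ndr_amplitude_uv": "ndr_amplitude",
    "ndr_group_delay_s": "ndr_group_delay",
    "ndr_onset_phase_rad": "ndr_onset_phase",
    "noise_sd_uv": "noise_sd",
    "one_over_f_weight": "one_over_f_weight",
    "clock_ratio": "clock_ratio",
    "reference_channel": "reference_channel",
}

_ANALYSIS_DEFAULTS = {
    "f0_list_hz": [37.0, 40.0, 43.0],
    "epoch_duration_s": 1.0,
    "montage_average": ["ipsi", "contra", "back"],
    "montage_reference": "cz",
    "f_threshold": F_RATIO_THRESHOLD,
    "n_side": 6,
    "mains_hz": 50.0,
}


@dataclass
class ScenarioConfig:
    """Validated scenario: synthetic recording + analysis + seed."""

    seed: int = 0
    recording: SyntheticEEGSpec = field(default_factory=SyntheticEEGSpec)
    analysis: dict = field(default_factory=lambda: dict(_ANALYSIS_DEFAULTS))
    output_dir: str | None = None

    @property
    def montage(self) -> Montage:
        return Montage(
            average=tuple(self.analysis["montage_average"]),
            reference=self.analysis["montage_reference"],
        )

    @classmethod
    def from_dict(cls, doc: dict) -> "ScenarioConfig":
        doc = dict(doc)
        unknown = set(doc) - {"seed", "recording", "analysis", "output_dir"}
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        rec_doc = dict(doc.get("recording", {}))
        unknown = set(rec_doc) - set(_RECORDING_KEYS)
        if unknown:
            raise ValueError(f"unknown recording keys: {sorted(unknown)}")
        rec_kwargs = {_RECORDING_KEYS[k]: v for k, v in rec_doc.items()}
        if "artefact_amplitudes" in rec_kwargs:
            rec_kwargs["artefact_amplitudes"] = {
                name: tuple(v)
                for name, v in rec_kwargs["artefact_amplitudes"].items()
            }
        analysis = dict(_ANALYSIS_DEFAULTS)
        an_doc = dict(doc.get("analysis", {}))
        unknown = set(an_doc) - set(_ANALYSIS_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown analysis keys: {sorted(unknown)}")
        analysis.update(an_doc)
        return cls(
            seed=int(doc.get("seed", 0)),
            recording=SyntheticEEGSpec(**rec_kwargs),
            analysis=analysis,
            output_dir=doc.get("output_dir"),
        )

    def to_dict(self) -> dict:
        rec = asdict(self.recording)
        inverse = {v: k for k, v in _RECORDING_KEYS.items()}
        rec_doc = {inverse[k]: v for k, v in rec.items()}
        return {
            "seed": self.seed,
            "recording": rec_doc,
            "analysis": dict(self.analysis),
            "output_dir": self.output_dir,
        }


def load_config(path) -> ScenarioConfig:
    """Load and validate a JSON (``.json``) or YAML (``.yml``/``.yaml``) config."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        doc = json.loads(text)
    elif path.suffix.lower() in (".yml", ".yaml"):
        doc = yaml.safe_load(text)
    else:
        raise ValueError(f"unrecognised config extension {path.suffix!r}")
    if not isinstance(doc, dict):
        raise ValueError("config document must be a mapping")
    return ScenarioConfig.from_dict(doc)


def dump_resolved_config(cfg: ScenarioConfig, path) -> None:
    """Write the fully resolved configuration (defaults included) as JSON."""
    Path(path).write_text(json.dumps(cfg.to_dict(), indent=1, sort_keys=True))
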