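"""Structured YAML/JSON configuration for a study run.

The config mirrors the clinical record fields: per-patient diameters (mm) and
either a preoperative MPV velocity or a postoperative MPV flow, the
segment-length defaults of the reduced geometry, the edge loss-model
parameters, the WSS thresholds, and an optional synthetic-cohort block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .anatomy import PatientRecord, SegmentLengths, patient_fixtures
from .hydraulics import EdgeLossModel
from .metrics import WssThresholds
from .synthetic import CohortSpec

__all__ = ["StudyConfig", "load_config", "default_config_dict", "dump_config"]


@dataclass
class StudyConfig:
    """Everything needed to run a study, resolved to domain objects."""

    patients: list[PatientRecord]
    lengths: SegmentLengths = field(default_factory=SegmentLengths)
    loss_model: EdgeLossModel = field(default_factory=EdgeLossModel)
    thresholds: WssThresholds = field(default_factory=WssThresholds)
    cohort: CohortSpec | None = None


def default_config_dict() -> dict:
    """The built-in configuration: the two study patients and all defaults."""
    patients = []
    for p in patient_fixtures():
        entry = {
            "id": p.id,
            "d_mpv": p.d_mpv,
            "d_sv": p.d_sv,
            "d_smv": p.d_smv,
            "d_lpv": p.d_lpv,
            "d_rpv": p.d_rpv,
            "p_pv": p.p_pv,
        }
        if p.v_mpv_pre is not None:
            entry["v_mpv_pre"] = p.v_mpv_pre
        if p.q_mpv_post is not None:
            entry["q_mpv_post"] = p.q_mpv_post
        patients.append(entry)
    return {
        "patients": patients,
        "segment_lengths": {
            "mpv_trunk": 0.040,
            "branch": 0.030,
            "tee_offset": 0.010,
            "shunt_entrance_losses": [0.45, 0.25],
        },
        "loss_model": {
            "regime_threshold": 2300.0,
            "k_contraction": 0.45,
            "k_bend": 0.25,
        },
        "wss_thresholds": {"low_venous": 6.0, "low_shunt": 10.0, "high": 15.0},
    }


def _parse(data: dict) -> StudyConfig:
    patients = [PatientRecord(**entry) for entry in data["patients"]]
    lengths_raw = dict(data.get("segment_lengths", {}))
    if "shunt_entrance_losses" in lengths_raw:
        lengths_raw["shunt_entrance_losses"] = tuple(
            lengths_raw["shunt_entrance_losses"]
        )
    cohort_raw = data.get("cohort")
    cohort = None
    if cohort_raw is not None:
        ranges = {
            k: (float(lo), float(hi))
            for k, (lo, hi) in cohort_raw.get("ranges", {}).items()
        }
        kwargs = {"n": cohort_raw["n"], "seed": cohort_raw["seed"]}
        if ranges:
            kwargs["ranges"] = ranges
        cohort = CohortSpec(**kwargs)
    return StudyConfig(
        patients=patients,
        lengths=SegmentLengths(**lengths_raw),
        loss_model=EdgeLossModel(**data.get("loss_model", {})),
        thresholds=WssThresholds(**data.get("wss_thresholds", {})),
        cohort=cohort,
    )


def load_config(path: str | Path | None = None) -> StudyConfig:
    """Load a study configuration; ``None`` loads the built-in defaults."""
    if path is None:
        return _parse(default_config_dict())
    data = yaml.safe_load(Path(path).read_text())
    return _parse(data)


def dump_config(path: str | Path) -> None:
    """Write the default configuration as a YAML template."""
    Path(path).write_text(
        yaml.safe_dump(default_config_dict(), sort_keys=False)
    )
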