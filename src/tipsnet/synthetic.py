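"""Synthetic patient records for testing the pipeline end to end.

Records are drawn uniformly inside closed physiological boxes anchored to the
two printed study patients: vessel diameters of adult portal anatomy,
preoperative MPV velocities in the portal-hypertensive range, and portal
pressures around the 25 mmHg population average. Uniform (rather than
normal) sampling keeps bound assertions exact; no distributional information
beyond the ranges is claimed.

A single integer seed governs a whole cohort; each record is drawn from a
substream keyed by (seed, index), so cohorts are order-independent and any
record can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .anatomy import PatientRecord

__all__ = ["CohortSpec", "sample_patient", "generate_cohort", "perturb_patient"]

#: Default sampling boxes (closed intervals) bracketing the printed patients.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "d_mpv": (14.0, 18.0),  # mm
    "d_sv": (8.0, 15.0),  # mm
    "d_smv": (10.0, 17.0),  # mm
    "d_lpv": (9.0, 13.0),  # mm
    "d_rpv": (8.0, 10.0),  # mm
    "v_mpv_pre": (0.1, 0.3),  # m/s
    "p_pv": (20.0, 30.0),  # mmHg
}

_FIELD_ORDER = ("d_mpv", "d_sv", "d_smv", "d_lpv", "d_rpv", "v_mpv_pre", "p_pv")


@dataclass(frozen=True)
class CohortSpec:
    """Size, seed and per-field sampling intervals of a synthetic cohort."""

    n: int
    seed: int
    ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES)
    )

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be at least 1")
        if set(self.ranges) != set(_FIELD_ORDER):
            raise ValueError(f"ranges must cover exactly {_FIELD_ORDER}")
        for name, (lo, hi) in self.ranges.items():
            if not (0 < lo <= hi):
                raise ValueError(f"range for {name} must be positive and nonempty")


def sample_patient(spec: CohortSpec, index: int) -> PatientRecord:
    """Draw one record; deterministic for fixed (spec.seed, index)."""
    if index < 0:
        raise ValueError("index must be nonnegative")
    rng = np.random.default_rng([spec.seed, index])
    values = {
        name: float(rng.uniform(*spec.ranges[name])) for name in _FIELD_ORDER
    }
    return PatientRecord(id=f"synthetic-{index:04d}", **values)


def generate_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """The cohort as a stable, reproducible list of records."""
    return [sample_patient(spec, i) for i in range(spec.n)]


def perturb_patient(
    patient: PatientRecord, relative_scale: float, seed: int
) -> PatientRecord:
    """Multiply each diameter and the flow datum by factors in [1-s, 1+s].

    A sensitivity harness: small ``relative_scale`` values probe solver
    robustness and smoothness of the downstream metrics.
    """
    if not 0 <= relative_scale < 0.5:
        raise ValueError("relative_scale must lie in [0, 0.5)")
    if relative_scale == 0:
        return patient
    rng = np.random.default_rng(seed)

    def factor() -> float:
        return float(rng.uniform(1.0 - relative_scale, 1.0 + relative_scale))

    updates = {
        name: getattr(patient, name) * factor()
        for name in ("d_mpv", "d_sv", "d_smv", "d_lpv", "d_rpv")
    }
    if patient.v_mpv_pre is not None:
        updates["v_mpv_pre"] = patient.v_mpv_pre * factor()
    if patient.q_mpv_post is not None:
        updates["q_mpv_post"] = patient.q_mpv_post * factor()
    return replace(patient, **updates)
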