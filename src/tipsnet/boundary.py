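"""Patient-specific boundary conditions for the portal network.

Three closures turn a sparse clinical record into a complete boundary set:

1. Preoperative MPV flow from the ultrasound velocity and the MPV
   cross-section, ``Q_pre = V_pre * A``.
2. The postoperative MPV flow is taken as twice the preoperative one, per
   clinical measurements after TIPS decompression.
3. Murray's law apportions flow among branches in proportion to the cube of
   the nominal diameter: the SV/SMV inlet split, and the LPV/RPV outlet
   resistances ``R_i = P_pv / (Q_pre * d_i^3 / (d_1^3 + d_2^3))`` with the
   portal pressure referenced to the zero-pressure IVC.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Optional

from .anatomy import PatientRecord, SimplificationType
from .units import mmhg_to_pa

__all__ = [
    "BoundarySet",
    "preop_mpv_flow",
    "postop_mpv_flow",
    "murray_split",
    "outlet_resistances",
    "assemble_boundary_set",
]


@dataclass(frozen=True)
class BoundarySet:
    """Derived inlet flows and outlet resistances for one patient.

    For simplification Type C the tributaries are absent and the combined
    inflow ``q_total`` is applied at the MPV inlet; ``q_sv``/``q_smv`` are
    then ``None``. Flows in m^3 s^-1, resistances in Pa s m^-3, sink pressure
    in Pa (always 0, the IVC reference).
    """

    q_total: float
    r_lpv: float
    r_rpv: float
    q_sv: Optional[float] = None
    q_smv: Optional[float] = None
    p_ivc: float = 0.0

    def __post_init__(self) -> None:
        if self.q_total < 0:
            raise ValueError("q_total must be nonnegative")
        if self.r_lpv <= 0 or self.r_rpv <= 0:
            raise ValueError("outlet resistances must be positive")
        if self.p_ivc != 0.0:
            raise ValueError("the IVC reference pressure is fixed at 0")
        if (self.q_sv is None) != (self.q_smv is None):
            raise ValueError("q_sv and q_smv must be given together")
        if self.q_sv is not None and self.q_sv + self.q_smv != self.q_total:
            raise ValueError("tributary flows must sum exactly to q_total")

    @property
    def flows(self) -> dict[str, float]:
        """Inflow values keyed as the network's inflow map expects."""
        if self.q_sv is None:
            return {"q_total": self.q_total}
        return {"q_sv": self.q_sv, "q_smv": self.q_smv, "q_total": self.q_total}

    def to_json(self) -> str:
        """Serialize with explicit SI unit tags."""
        payload = {k: v for k, v in asdict(self).items()}
        payload["units"] = {
            "q_total": "m^3 s^-1",
            "q_sv": "m^3 s^-1",
            "q_smv": "m^3 s^-1",
            "r_lpv": "Pa s m^-3",
            "r_rpv": "Pa s m^-3",
            "p_ivc": "Pa",
        }
        return json.dumps(payload, sort_keys=True)


def preop_mpv_flow(v_mpv_pre: float, d_mpv: float) -> float:
    """Preoperative MPV volumetric flow from velocity and diameter (SI units).

    ``v * pi d^2 / 4`` with ``v`` in m/s and ``d`` in m.
    """
    if v_mpv_pre <= 0 or d_mpv <= 0:
        raise ValueError("velocity and diameter must be positive")
    return v_mpv_pre * math.pi * d_mpv * d_mpv / 4.0


def postop_mpv_flow(q_pre: float) -> float:
    """Postoperative MPV flow: twice the preoperative flow."""
    if q_pre <= 0:
        raise ValueError("q_pre must be positive")
    return 2.0 * q_pre


def murray_split(q_total: float, d_a: float, d_b: float) -> tuple[float, float]:
    """Split a flow between two branches by the cube of their diameters.

    Diameter units cancel; any consistent unit may be used. The two outputs
    sum to ``q_total`` exactly (the second is computed by difference).
    """
    if d_a <= 0 or d_b <= 0:
        raise ValueError("diameters must be positive")
    if q_total < 0:
        raise ValueError("q_total must be nonnegative")
    frac_a = d_a**3 / (d_a**3 + d_b**3)
    q_a = q_total * frac_a
    q_b = q_total - q_a
    # Re-derive by difference until the pair sums to q_total bitwise; one or
    # two passes always suffice for finite positive inputs.
    for _ in range(2):
        if q_a + q_b == q_total:
            break
        q_a = q_total - q_b
        q_b = q_total - q_a
    return q_a, q_b


def outlet_resistances(
    p_pv: float, q_mpv_pre: float, d_lpv: float, d_rpv: float
) -> tuple[float, float]:
    """Close the LPV/RPV outlet resistances against the portal pressure.

    ``R_i = P_pv / (Q_pre * d_i^3 / (d_1^3 + d_2^3))`` with ``p_pv`` in mmHg
    (converted at 133.322 Pa/mmHg), ``q_mpv_pre`` in m^3/s and diameters in
    any consistent unit.
    """
    if min(p_pv, q_mpv_pre, d_lpv, d_rpv) <= 0:
        raise ValueError("all inputs must be positive")
    p_pa = mmhg_to_pa(p_pv)
    q_lpv, q_rpv = murray_split(q_mpv_pre, d_lpv, d_rpv)
    return p_pa / q_lpv, p_pa / q_rpv


def assemble_boundary_set(
    patient: PatientRecord, simplification: SimplificationType
) -> BoundarySet:
    """Compose the closures into the boundary set for one study case.

    The result is identical for all cases of a patient except that Type C
    replaces the SV/SMV pair by the single combined inflow.
    """
    q_pre = patient.q_mpv_pre
    q_total = patient.q_mpv_post_total
    r_lpv, r_rpv = outlet_resistances(
        patient.p_pv, q_pre, patient.d_lpv, patient.d_rpv
    )
    if simplification.label == "C":
        return BoundarySet(q_total=q_total, r_lpv=r_lpv, r_rpv=r_rpv)
    q_sv, q_smv = murray_split(q_total, patient.d_sv, patient.d_smv)
    return BoundarySet(
        q_total=q_total, r_lpv=r_lpv, r_rpv=r_rpv, q_sv=q_sv, q_smv=q_smv
    )
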