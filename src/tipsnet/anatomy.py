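"""Parametric anatomy of the portal venous system after TIPS placement.

The portal system is reduced to a directed network of cylindrical vessel
segments: the splenic vein (SV) and superior mesenteric vein (SMV) merge into
the main portal vein (MPV), which bifurcates into the left and right portal
veins (LPV, RPV); each intrahepatic branch drains through a lumped resistance
into the inferior vena cava (IVC), the zero-pressure reference. The TIPS stent
(8 mm x 60 mm by default) tees off the MPV trunk just upstream of the
bifurcation, or off the LPV/RPV just downstream of it, and discharges directly
into the IVC.

Three geometric simplification strategies are represented: Type A keeps long
SV/SMV tributaries, Type B shortens them, and Type C removes them entirely,
applying the combined inflow at an MPV inlet stub. Two patients x three shunt
positions x three simplification types yield the 18-case study design.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

import networkx as nx

from .units import mm_to_m

__all__ = [
    "FluidProperties",
    "BLOOD",
    "PatientRecord",
    "ShuntPosition",
    "ShuntConfig",
    "SimplificationType",
    "SegmentLengths",
    "VesselSegment",
    "FlowNetwork",
    "CaseSpec",
    "SINK",
    "patient_fixtures",
    "enumerate_cases",
    "build_network",
]

#: Label of the zero-pressure reference node (inferior vena cava).
SINK = "ivc"


@dataclass(frozen=True)
class FluidProperties:
    """Bulk properties of blood treated as a Newtonian fluid.

    Parameters
    ----------
    density : float
        Mass density in kg m^-3.
    dynamic_viscosity : float
        Dynamic viscosity in Pa s.
    """

    density: float = 1060.0
    dynamic_viscosity: float = 0.0035

    def __post_init__(self) -> None:
        if self.density <= 0 or self.dynamic_viscosity <= 0:
            raise ValueError("density and dynamic_viscosity must be positive")


#: Blood at the standard values used for the study.
BLOOD = FluidProperties()


@dataclass(frozen=True)
class PatientRecord:
    """Per-patient anatomy and physiology.

    Diameters are nominal vessel diameters in millimetres, as printed in
    clinical records. Exactly one of ``v_mpv_pre`` (preoperative area-averaged
    MPV velocity, m/s) and ``q_mpv_post`` (postoperative MPV volumetric flow,
    m^3/s) may be absent; each is derivable from the other through the MPV
    cross-section and the post/pre flow-doubling rule.
    """

    id: str
    d_mpv: float
    d_sv: float
    d_smv: float
    d_lpv: float
    d_rpv: float
    v_mpv_pre: Optional[float] = None
    q_mpv_post: Optional[float] = None
    p_pv: float = 25.0  # preoperative portal pressure estimate, mmHg

    def __post_init__(self) -> None:
        for name in ("d_mpv", "d_sv", "d_smv", "d_lpv", "d_rpv"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.v_mpv_pre is None and self.q_mpv_post is None:
            raise ValueError("one of v_mpv_pre / q_mpv_post is required")
        if self.v_mpv_pre is not None and self.v_mpv_pre <= 0:
            raise ValueError("v_mpv_pre must be positive")
        if self.q_mpv_post is not None and self.q_mpv_post <= 0:
            raise ValueError("q_mpv_post must be positive")
        if self.p_pv <= 0:
            raise ValueError("p_pv must be positive")

    @property
    def q_mpv_pre(self) -> float:
        """Preoperative MPV volumetric flow in m^3 s^-1.

        Taken as velocity x MPV cross-sectional area when the velocity is
        recorded, otherwise as half the postoperative flow.
        """
        if self.v_mpv_pre is not None:
            d = mm_to_m(self.d_mpv)
            return self.v_mpv_pre * math.pi * d * d / 4.0
        assert self.q_mpv_post is not None
        return self.q_mpv_post / 2.0

    @property
    def q_mpv_post_total(self) -> float:
        """Postoperative MPV volumetric flow (twice the preoperative one)."""
        if self.q_mpv_post is not None:
            return self.q_mpv_post
        return 2.0 * self.q_mpv_pre


class ShuntPosition(str, Enum):
    """Candidate placement of the TIPS stent."""

    LPV = "LPV"
    MPV = "MPV"
    RPV = "RPV"


@dataclass(frozen=True)
class ShuntConfig:
    """Geometry of the TIPS stent.

    ``inlet_offset`` is the distance from the shunt entrance to the inlet
    probe plane (the clinical pressure probe sits 50 mm from the outlet of
    the 60 mm stent, i.e. 10 mm from the entrance).
    """

    position: ShuntPosition
    diameter: float = 0.008
    length: float = 0.060
    inlet_offset: float = 0.010

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.length <= 0:
            raise ValueError("shunt diameter and length must be positive")
        if not 0 <= self.inlet_offset < self.length:
            raise ValueError("inlet_offset must lie within the shunt length")

    @property
    def area(self) -> float:
        return math.pi * self.diameter**2 / 4.0


@dataclass(frozen=True)
class SimplificationType:
    """Geometric simplification strategy for the SV/SMV tributaries.

    Type A keeps long tributaries, Type B shorter ones, Type C none (the
    combined inflow is applied at the MPV inlet stub). Lengths in metres.
    """

    label: str
    l_sv: float
    l_smv: float

    def __post_init__(self) -> None:
        if self.label not in ("A", "B", "C"):
            raise ValueError("label must be one of A, B, C")
        if self.label == "C":
            if self.l_sv != 0.0 or self.l_smv != 0.0:
                raise ValueError("Type C has no SV/SMV segments")
        elif self.l_sv <= 0 or self.l_smv <= 0:
            raise ValueError("tributary lengths must be positive")

    @classmethod
    def type_a(cls) -> "SimplificationType":
        return cls("A", 0.080, 0.100)

    @classmethod
    def type_b(cls) -> "SimplificationType":
        return cls("B", 0.030, 0.040)

    @classmethod
    def type_c(cls) -> "SimplificationType":
        return cls("C", 0.0, 0.0)

    @classmethod
    def default_types(cls) -> tuple["SimplificationType", ...]:
        return (cls.type_a(), cls.type_b(), cls.type_c())


@dataclass(frozen=True)
class SegmentLengths:
    """Default centerline lengths of the reduced segments, in metres.

    The downstream results are insensitive to these because the inflows are
    prescribed; friction in the slow upstream segments contributes well under
    1% of the portal pressure gradient.
    """

    mpv_trunk: float = 0.040
    branch: float = 0.030  # intrahepatic LPV/RPV
    tee_offset: float = 0.010  # shunt tee distance from the bifurcation
    #: Minor-loss factors at the shunt entrance: sudden contraction into the
    #: 8 mm stent and the bend of the intrahepatic tract.
    shunt_entrance_losses: tuple[float, ...] = (0.45, 0.25)

    def __post_init__(self) -> None:
        if min(self.mpv_trunk, self.branch, self.tee_offset) <= 0:
            raise ValueError("segment lengths must be positive")
        if self.tee_offset >= self.branch:
            raise ValueError("tee_offset must be shorter than the branch")
        if 2 * self.tee_offset >= self.mpv_trunk:
            raise ValueError("tee_offset must fit in half the MPV trunk")
        if any(k < 0 for k in self.shunt_entrance_losses):
            raise ValueError("loss coefficients must be nonnegative")


@dataclass(frozen=True)
class VesselSegment:
    """A cylindrical conduit with optional entrance effects.

    ``loss_coefficients`` are dimensionless minor-loss factors K applied at
    the segment entrance. ``upstream_diameter``, when set, adds a Bernoulli
    static-pressure correction for the area change from the parent conduit.
    ``is_shunt`` marks segments belonging to the TIPS stent.
    """

    name: str
    diameter: float
    length: float
    loss_coefficients: tuple[float, ...] = ()
    upstream_diameter: Optional[float] = None
    is_shunt: bool = False

    def __post_init__(self) -> None:
        if self.diameter < 0 or self.length < 0:
            raise ValueError("diameter and length must be nonnegative")
        if any(k < 0 for k in self.loss_coefficients):
            raise ValueError("loss coefficients must be nonnegative")


@dataclass(frozen=True)
class CaseSpec:
    """One cell of the study design: patient x shunt position x type."""

    patient: PatientRecord
    shunt: ShuntConfig
    simplification: SimplificationType

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.patient.id, self.shunt.position.value, self.simplification.label)


@dataclass
class FlowNetwork:
    """Directed graph of vessel segments, the shunt, and resistance outlets.

    Segment edges carry a :class:`VesselSegment` under the ``segment`` edge
    attribute; outlet edges carry a linear ``resistance`` (Pa s m^-3) to the
    sink. ``inflows`` maps each inflow node to the boundary-set flow key that
    feeds it.
    """

    graph: nx.DiGraph
    inflows: dict[str, str]
    outlet_resistances: dict[str, float]
    case: CaseSpec
    sink: str = SINK
    probes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.probes.setdefault("mpv_midsection", "mpv_mid")
        self.probes.setdefault("shunt_inlet", "shunt_inlet")
        self.probes.setdefault("shunt_outlet", self.sink)
        self.probes.setdefault("sink", self.sink)

    def resolve(self, probe: str) -> str:
        """Resolve a probe alias or node label to a graph node."""
        node = self.probes.get(probe, probe)
        if node not in self.graph:
            raise KeyError(f"unknown probe or node: {probe!r}")
        return node

    def segment_edges(self) -> list[tuple[str, str, VesselSegment]]:
        return [
            (u, v, data["segment"])
            for u, v, data in self.graph.edges(data=True)
            if "segment" in data
        ]

    def shunt_edges(self) -> list[tuple[str, str, VesselSegment]]:
        return [(u, v, s) for u, v, s in self.segment_edges() if s.is_shunt]

    def n_shunt_conduits(self) -> int:
        """Number of contiguous shunt chains (must be exactly one)."""
        sub = nx.DiGraph()
        sub.add_edges_from((u, v) for u, v, _ in self.shunt_edges())
        if sub.number_of_edges() == 0:
            return 0
        return nx.number_weakly_connected_components(sub)

    def validate(self) -> None:
        """Check the structural invariants; raise ``ValueError`` on failure."""
        g = self.graph
        if not nx.is_weakly_connected(g):
            raise ValueError("network is not connected")
        for node in self.inflows:
            if g.degree(node) != 1:
                raise ValueError(f"inflow node {node} must have one incident edge")
            if not nx.has_path(g, node, self.sink):
                raise ValueError(f"sink unreachable from inflow node {node}")
        if self.n_shunt_conduits() != 1:
            raise ValueError("network must contain exactly one shunt conduit")
        shunt_targets = {v for _, v, _ in self.shunt_edges()}
        if self.sink not in shunt_targets:
            raise ValueError("shunt must discharge into the sink")
        if set(self.outlet_resistances) != {
            u for u, v, d in g.edges(data=True) if "resistance" in d
        }:
            raise ValueError("outlet resistance map inconsistent with edges")


def patient_fixtures() -> tuple[PatientRecord, PatientRecord]:
    """The two study patients, with printed diameters and postoperative flows.

    Patient #1 has a relatively straight splenic vein, Patient #2 a curved
    one; both carry the population-averaged preoperative portal pressure of
    25 mmHg, since the in vivo measurements were missing.
    """
    p1 = PatientRecord(
        id="patient-1",
        d_mpv=16.45,
        d_sv=8.98,
        d_smv=10.38,
        d_lpv=9.60,
        d_rpv=8.96,
        q_mpv_post=7.86e-5,
        p_pv=25.0,
    )
    p2 = PatientRecord(
        id="patient-2",
        d_mpv=16.27,
        d_sv=14.18,
        d_smv=16.08,
        d_lpv=12.92,
        d_rpv=9.75,
        q_mpv_post=8.73e-5,
        p_pv=25.0,
    )
    return p1, p2


def enumerate_cases(
    patients: list[PatientRecord] | tuple[PatientRecord, ...],
    shunt: ShuntConfig | None = None,
    types: tuple[SimplificationType, ...] | None = None,
) -> list[CaseSpec]:
    """Enumerate the study design as a stable Cartesian product.

    Order: patients in the given order, then shunt positions LPV, MPV, RPV,
    then simplification types A, B, C (innermost). Two patients yield the
    18-case design.
    """
    if not patients:
        raise ValueError("at least one patient is required")
    if types is None:
        types = SimplificationType.default_types()
    cases = []
    for patient, position, simp in itertools.product(
        patients, (ShuntPosition.LPV, ShuntPosition.MPV, ShuntPosition.RPV), types
    ):
        cfg = (
            ShuntConfig(position=position)
            if shunt is None
            else replace(shunt, position=position)
        )
        cases.append(CaseSpec(patient=patient, shunt=cfg, simplification=simp))
    return cases


def build_network(case: CaseSpec, defaults: SegmentLengths | None = None) -> FlowNetwork:
    """Assemble the flow network for one study case.

    The MPV trunk is split at its midpoint by the pressure probe node. For
    shunt position MPV the stent tees off the trunk ``tee_offset`` upstream of
    the bifurcation; for LPV/RPV it tees off the named branch ``tee_offset``
    downstream of it. The stent is represented as a two-edge chain (entrance
    piece up to the inlet probe plane, then body) discharging directly into
    the IVC sink. Outlet resistances are closed from the patient's portal
    pressure and diameter-cubed flow split.
    """
    if defaults is None:
        defaults = SegmentLengths()
    from .boundary import outlet_resistances  # local import avoids a cycle

    patient = case.patient
    shunt = case.shunt
    simp = case.simplification
    position = shunt.position

    d_mpv = mm_to_m(patient.d_mpv)
    d_lpv = mm_to_m(patient.d_lpv)
    d_rpv = mm_to_m(patient.d_rpv)
    r_lpv, r_rpv = outlet_resistances(
        patient.p_pv, patient.q_mpv_pre, patient.d_lpv, patient.d_rpv
    )

    g = nx.DiGraph()
    half = defaults.mpv_trunk / 2.0

    def seg(u: str, v: str, segment: VesselSegment) -> None:
        g.add_edge(u, v, segment=segment)

    # Inflow tributaries (upstream of the MPV inlet junction).
    if simp.label == "C":
        inflows = {"pv_in": "q_total"}
        seg("pv_in", "mpv_inlet", VesselSegment("mpv_inlet_stub", d_mpv, 0.0))
    else:
        inflows = {"sv_in": "q_sv", "smv_in": "q_smv"}
        seg("sv_in", "mpv_inlet", VesselSegment("sv", mm_to_m(patient.d_sv), simp.l_sv))
        seg(
            "smv_in",
            "mpv_inlet",
            VesselSegment("smv", mm_to_m(patient.d_smv), simp.l_smv),
        )

    # MPV trunk, split at the midsection probe (and at the tee for position MPV).
    if position is ShuntPosition.MPV:
        seg("mpv_inlet", "mpv_mid", VesselSegment("mpv_up", d_mpv, half))
        seg(
            "mpv_mid",
            "shunt_tee",
            VesselSegment("mpv_mid_tee", d_mpv, half - defaults.tee_offset),
        )
        seg(
            "shunt_tee",
            "bifurcation",
            VesselSegment("mpv_tee_bif", d_mpv, defaults.tee_offset),
        )
        host_diameter = d_mpv
    else:
        seg("mpv_inlet", "mpv_mid", VesselSegment("mpv_up", d_mpv, half))
        seg("mpv_mid", "bifurcation", VesselSegment("mpv_down", d_mpv, half))
        host_diameter = d_lpv if position is ShuntPosition.LPV else d_rpv

    # Intrahepatic branches, with the Bernoulli area-change correction at
    # their entrance (parent conduit is the MPV trunk).
    def branch(name: str, d: float, outlet: str, hosts_shunt: bool) -> None:
        if hosts_shunt:
            seg(
                "bifurcation",
                "shunt_tee",
                VesselSegment(
                    f"{name}_tee", d, defaults.tee_offset, upstream_diameter=d_mpv
                ),
            )
            seg(
                "shunt_tee",
                outlet,
                VesselSegment(f"{name}_out", d, defaults.branch - defaults.tee_offset),
            )
        else:
            seg(
                "bifurcation",
                outlet,
                VesselSegment(name, d, defaults.branch, upstream_diameter=d_mpv),
            )

    branch("lpv", d_lpv, "lpv_out", hosts_shunt=position is ShuntPosition.LPV)
    branch("rpv", d_rpv, "rpv_out", hosts_shunt=position is ShuntPosition.RPV)

    # The shunt chain: entrance piece (contraction + bend + area change) up to
    # the inlet probe plane, then the body straight into the IVC.
    seg(
        "shunt_tee",
        "shunt_inlet",
        VesselSegment(
            "shunt_entrance",
            shunt.diameter,
            shunt.inlet_offset,
            loss_coefficients=tuple(defaults.shunt_entrance_losses),
            upstream_diameter=host_diameter,
            is_shunt=True,
        ),
    )
    seg(
        "shunt_inlet",
        SINK,
        VesselSegment(
            "shunt_body",
            shunt.diameter,
            shunt.length - shunt.inlet_offset,
            is_shunt=True,
        ),
    )

    # Resistance outlets into the IVC.
    g.add_edge("lpv_out", SINK, resistance=r_lpv)
    g.add_edge("rpv_out", SINK, resistance=r_rpv)

    network = FlowNetwork(
        graph=g,
        inflows=inflows,
        outlet_resistances={"lpv_out": r_lpv, "rpv_out": r_rpv},
        case=case,
    )
    network.validate()
    return network
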