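"""Per-case clinical metrics and the 18-case comparison study.

The headline quantities mirror what interventional planning cares about: the
portal pressure gradient (PPG, MPV-midsection pressure over the zero IVC
reference, in mmHg; clinical decompression threshold 12 mmHg), the
area-averaged shunt velocity and its Reynolds number, probe pressures at the
shunt inlet/outlet, and segment-mean wall shear stress (WSS) classified
against low/high thresholds (6 Pa on venous walls and 10 Pa on the stent wall
for "low", 15 Pa for "high"). A generic relative-error comparator quantifies
how much the geometric simplification (Types B/C vs the reference Type A)
moves each metric.

Segment-mean WSS replaces the 3D wall-area statistics (ALWSS/AHWSS) that only
a spatially resolved solve can produce; the comparator applies to those too
when values are supplied externally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .anatomy import (
    BLOOD,
    CaseSpec,
    FlowNetwork,
    FluidProperties,
    SegmentLengths,
    SimplificationType,
    build_network,
    enumerate_cases,
)
from .boundary import assemble_boundary_set
from .hydraulics import EdgeLossModel, reynolds, wall_shear
from .solver import NetworkSolution, solve
from .units import pa_to_mmhg

__all__ = [
    "WssThresholds",
    "CaseResult",
    "StudyTable",
    "case_metrics",
    "relative_error",
    "study_table",
    "write_report",
    "run_case",
    "run_study",
]

#: Metrics compared across simplification types in the study table.
COMPARED_METRICS = ("ppg", "shunt_velocity")


@dataclass(frozen=True)
class WssThresholds:
    """WSS classification thresholds in Pa (config-exposed)."""

    low_venous: float = 6.0
    low_shunt: float = 10.0
    high: float = 15.0


@dataclass(frozen=True)
class CaseResult:
    """Scalar metrics extracted from one converged case."""

    patient: str
    position: str
    simplification: str
    ppg: float  # mmHg
    shunt_velocity: float  # m/s
    shunt_flow_fraction: float
    p_shunt_inlet: float  # Pa
    p_shunt_outlet: float  # Pa
    shunt_re: float
    segment_wss: dict[str, float] = field(default_factory=dict)
    wss_class: dict[str, str] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.patient, self.position, self.simplification)


def classify_wss(
    tau: float, is_shunt_wall: bool, thresholds: WssThresholds = WssThresholds()
) -> str:
    """Threshold classification of a segment-mean WSS value."""
    low = thresholds.low_shunt if is_shunt_wall else thresholds.low_venous
    if tau < low:
        return "low"
    if tau > thresholds.high:
        return "high"
    return "normal"


def case_metrics(
    case: CaseSpec,
    network: FlowNetwork,
    solution: NetworkSolution,
    fluid: FluidProperties = BLOOD,
    model: EdgeLossModel = EdgeLossModel(),
    thresholds: WssThresholds = WssThresholds(),
) -> CaseResult:
    """Extract the per-case metrics from a converged network solution."""
    if not solution.converged:
        raise ValueError("case metrics require a converged solution")

    q_shunt = sum(
        solution.edge_flows[(u, v)] for u, v, s in network.shunt_edges() if v == network.sink
    )
    q_total = sum(
        solution.edge_flows[next(iter(network.graph.out_edges(n)))]
        for n in network.inflows
    )
    shunt = case.shunt
    v_shunt = q_shunt / shunt.area

    segment_wss: dict[str, float] = {}
    wss_class: dict[str, str] = {}
    for u, v, seg in sorted(network.segment_edges(), key=lambda t: t[2].name):
        if seg.length == 0:
            continue  # zero-size stubs have no wall
        tau = wall_shear(abs(solution.edge_flows[(u, v)]), seg.diameter, fluid, model)
        segment_wss[seg.name] = tau
        wss_class[seg.name] = classify_wss(tau, seg.is_shunt, thresholds)

    return CaseResult(
        patient=case.patient.id,
        position=shunt.position.value,
        simplification=case.simplification.label,
        ppg=pa_to_mmhg(solution.pressure("mpv_midsection")),
        shunt_velocity=v_shunt,
        shunt_flow_fraction=q_shunt / q_total if q_total else 0.0,
        p_shunt_inlet=solution.pressure("shunt_inlet"),
        p_shunt_outlet=solution.pressure("shunt_outlet"),
        shunt_re=reynolds(q_shunt, shunt.diameter, fluid),
        segment_wss=segment_wss,
        wss_class=wss_class,
    )


def relative_error(x: float, x_ref: float) -> float:
    """Relative error of ``x`` against a reference, in percent.

    ``(x - x_ref) / x_ref * 100`` — the comparator used for Type B/C results
    against the Type A reference (and for externally supplied wall-area
    statistics).
    """
    if x_ref == 0:
        raise ZeroDivisionError("relative error undefined for zero reference")
    return (x - x_ref) / x_ref * 100.0


@dataclass
class StudyTable:
    """The full study: one row per case plus B/C-vs-A relative errors.

    ``relative_errors`` maps (patient, position, simplification, metric) to
    the percent error against the Type A row; Type A rows carry no entry.
    """

    rows: dict[tuple[str, str, str], CaseResult]
    relative_errors: dict[tuple[str, str, str, str], float]

    def max_abs_error(self, patient: str, metric: str) -> float:
        """Largest |relative error| of a metric across a patient's cases."""
        vals = [
            abs(v)
            for (pat, _, _, met), v in self.relative_errors.items()
            if pat == patient and met == metric
        ]
        if not vals:
            raise KeyError(f"no errors recorded for {patient!r}/{metric!r}")
        return max(vals)

    def to_frame(self) -> pd.DataFrame:
        """One row per case, stable column order, units in headers."""
        records = []
        for key in sorted(self.rows):
            r = self.rows[key]
            records.append(
                {
                    "patient": r.patient,
                    "shunt_position": r.position,
                    "simplification": r.simplification,
                    "ppg_mmhg": r.ppg,
                    "shunt_velocity_m_s": r.shunt_velocity,
                    "shunt_flow_fraction": r.shunt_flow_fraction,
                    "shunt_re": r.shunt_re,
                    "p_shunt_inlet_pa": r.p_shunt_inlet,
                    "p_shunt_outlet_pa": r.p_shunt_outlet,
                    "ppg_rel_err_pct": self.relative_errors.get(key + ("ppg",)),
                    "shunt_velocity_rel_err_pct": self.relative_errors.get(
                        key + ("shunt_velocity",)
                    ),
                }
            )
        return pd.DataFrame.from_records(records)

    def to_nested_dict(self) -> dict:
        """Nested patient -> position -> type mapping, JSON-ready."""
        out: dict = {}
        for (patient, position, simp), r in sorted(self.rows.items()):
            entry = {
                "ppg_mmhg": r.ppg,
                "shunt_velocity_m_s": r.shunt_velocity,
                "shunt_flow_fraction": r.shunt_flow_fraction,
                "shunt_re": r.shunt_re,
                "p_shunt_inlet_pa": r.p_shunt_inlet,
                "p_shunt_outlet_pa": r.p_shunt_outlet,
                "segment_wss_pa": r.segment_wss,
                "wss_class": r.wss_class,
                "relative_errors_pct": {
                    met: self.relative_errors[(patient, position, simp, met)]
                    for met in COMPARED_METRICS
                    if (patient, position, simp, met) in self.relative_errors
                },
            }
            out.setdefault(patient, {}).setdefault(position, {})[simp] = entry
        return out

    @classmethod
    def from_nested_dict(cls, data: dict) -> "StudyTable":
        rows = {}
        errors = {}
        for patient, positions in data.items():
            for position, simps in positions.items():
                for simp, entry in simps.items():
                    rows[(patient, position, simp)] = CaseResult(
                        patient=patient,
                        position=position,
                        simplification=simp,
                        ppg=entry["ppg_mmhg"],
                        shunt_velocity=entry["shunt_velocity_m_s"],
                        shunt_flow_fraction=entry["shunt_flow_fraction"],
                        p_shunt_inlet=entry["p_shunt_inlet_pa"],
                        p_shunt_outlet=entry["p_shunt_outlet_pa"],
                        shunt_re=entry["shunt_re"],
                        segment_wss=dict(entry["segment_wss_pa"]),
                        wss_class=dict(entry["wss_class"]),
                    )
                    for met, val in entry.get("relative_errors_pct", {}).items():
                        errors[(patient, position, simp, met)] = val
        return cls(rows=rows, relative_errors=errors)


def study_table(results: list[CaseResult]) -> StudyTable:
    """Assemble case results and the B/C-vs-A relative errors.

    Requires the complete design: every (patient, position) group must hold
    exactly the three simplification types.
    """
    rows = {r.key: r for r in results}
    if len(rows) != len(results):
        raise ValueError("duplicate case keys in results")
    groups: dict[tuple[str, str], set[str]] = {}
    for patient, position, simp in rows:
        groups.setdefault((patient, position), set()).add(simp)
    for key, simps in groups.items():
        if simps != {"A", "B", "C"}:
            raise ValueError(f"incomplete simplification set for {key}: {simps}")

    errors: dict[tuple[str, str, str, str], float] = {}
    for patient, position in groups:
        ref = rows[(patient, position, "A")]
        for simp in ("B", "C"):
            r = rows[(patient, position, simp)]
            for metric in COMPARED_METRICS:
                errors[(patient, position, simp, metric)] = relative_error(
                    getattr(r, metric), getattr(ref, metric)
                )
    return StudyTable(rows=rows, relative_errors=errors)


def write_report(
    table: StudyTable, csv_path: str | Path, json_path: str | Path
) -> None:
    """Write the study as CSV (one row per case) and nested JSON.

    Output bytes are deterministic for a fixed table.
    """
    csv_path, json_path = Path(csv_path), Path(json_path)
    table.to_frame().to_csv(csv_path, index=False, lineterminator="\n")
    json_path.write_text(
        json.dumps(table.to_nested_dict(), sort_keys=True, indent=1) + "\n"
    )


def run_case(
    case: CaseSpec,
    lengths: SegmentLengths | None = None,
    fluid: FluidProperties = BLOOD,
    model: EdgeLossModel = EdgeLossModel(),
    thresholds: WssThresholds = WssThresholds(),
    tolerance: float = 1e-12,
) -> tuple[FlowNetwork, NetworkSolution, CaseResult]:
    """Build, solve and summarize one study case."""
    network = build_network(case, lengths)
    boundary = assemble_boundary_set(case.patient, case.simplification)
    solution = solve(network, boundary, fluid, model, tolerance=tolerance)
    result = case_metrics(case, network, solution, fluid, model, thresholds)
    return network, solution, result


def run_study(
    patients,
    lengths: SegmentLengths | None = None,
    fluid: FluidProperties = BLOOD,
    model: EdgeLossModel = EdgeLossModel(),
    thresholds: WssThresholds = WssThresholds(),
    types: tuple[SimplificationType, ...] | None = None,
) -> StudyTable:
    """Run the full positions x simplifications design for the given patients."""
    results = []
    for case in enumerate_cases(patients, types=types):
        _, _, result = run_case(case, lengths, fluid, model, thresholds)
        results.append(result)
    return study_table(results)
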