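"""Network solver: closed forms, conservation, and route agreement."""

import dataclasses

import networkx as nx
import pytest

from tipsnet.anatomy import (
    FlowNetwork,
    ShuntConfig,
    ShuntPosition,
    VesselSegment,
    build_network,
    enumerate_cases,
)
from tipsnet.boundary import assemble_boundary_set
from tipsnet.solver import (
    pressure_at,
    residual_report,
    solve,
    solve_newton,
    solve_path_reduction,
)


def _tiny_network(graph, inflows, resistances):
    return FlowNetwork(
        graph=graph,
        inflows=inflows,
        outlet_resistances=resistances,
        case=None,
        probes={"shunt_inlet": "ivc", "mpv_midsection": "ivc"},
    )


class TestClosedForms:
    def test_single_resistor_ohm_analogue(self):
        g = nx.DiGraph()
        g.add_edge("in", "ivc", resistance=2e8)
        net = _tiny_network(g, {"in": "q_total"}, {"in": 2e8})
        sol = solve(net, {"q_total": 6e-5})
        assert sol.converged
        assert sol.node_pressures["in"] == pytest.approx(6e-5 * 2e8, rel=1e-12)

    def test_two_parallel_resistors_split(self):
        r1, r2, q = 2e8, 1e8, 6e-5
        g = nx.DiGraph()
        g.add_edge("in", "n", segment=VesselSegment("feed", 0.01, 0.0))
        g.add_edge("n", "a", segment=VesselSegment("la", 0.01, 0.0))
        g.add_edge("n", "b", segment=VesselSegment("lb", 0.01, 0.0))
        g.add_edge("a", "ivc", resistance=r1)
        g.add_edge("b", "ivc", resistance=r2)
        net = _tiny_network(g, {"in": "q_total"}, {"a": r1, "b": r2})
        sol = solve(net, {"q_total": q})
        assert sol.edge_flows[("a", "ivc")] == pytest.approx(q * r2 / (r1 + r2), rel=1e-9)
        assert sol.edge_flows[("b", "ivc")] == pytest.approx(q * r1 / (r1 + r2), rel=1e-9)
        assert sol.node_pressures["n"] == pytest.approx(q * r1 * r2 / (r1 + r2), rel=1e-9)


class TestHeadlineCase:
    def test_shunt_flow_and_mpv_pressure(self, headline_case):
        # The one-dimensional balance of shunt-path losses against the
        # resistive hepatic path puts the shunt flow near 6.09e-5 m^3/s and
        # the MPV static pressure near 1.5 kPa.
        _, network, solution, _ = headline_case
        q_shunt = solution.edge_flows[("shunt_inlet", "ivc")]
        assert q_shunt == pytest.approx(6.09e-5, rel=0.01)
        assert solution.node_pressures["mpv_mid"] == pytest.approx(1.50e3, rel=0.03)

    def test_probe_pressures(self, headline_case):
        _, _, solution, _ = headline_case
        assert pressure_at(solution, "sink") == 0.0
        assert pressure_at(solution, "shunt_outlet") == 0.0
        assert pressure_at(solution, "mpv_midsection", mmhg=True) == pytest.approx(
            11.2, abs=0.5
        )
        with pytest.raises(KeyError):
            pressure_at(solution, "no_such_probe")


class TestRouteAgreement:
    def test_newton_matches_path_reduction_on_all_cases(self, patients):
        for case in enumerate_cases(list(patients)):
            net = build_network(case)
            bset = assemble_boundary_set(case.patient, case.simplification)
            newton = solve_newton(net, bset)
            ref = solve_path_reduction(net, bset)
            q_n = newton.edge_flows[("shunt_inlet", "ivc")]
            q_r = ref.edge_flows[("shunt_inlet", "ivc")]
            assert q_n == pytest.approx(q_r, rel=1e-8)
            for node in newton.node_pressures:
                assert newton.node_pressures[node] == pytest.approx(
                    ref.node_pressures[node], rel=1e-6, abs=1e-6
                )


class TestConservationAndDiagnostics:
    def test_global_and_nodal_conservation(self, headline_case, patients):
        case, network, solution, _ = headline_case
        bset = assemble_boundary_set(case.patient, case.simplification)
        report = residual_report(network, bset, solution)
        assert max(abs(v) for v in report.values()) <= 1e-12
        outflow = sum(
            solution.edge_flows[e] for e in network.graph.in_edges("ivc")
        )
        assert outflow == pytest.approx(bset.q_total, rel=1e-12)

    def test_residual_report_max_matches_solution_norm(self, headline_case):
        case, network, solution, _ = headline_case
        bset = assemble_boundary_set(case.patient, case.simplification)
        report = residual_report(network, bset, solution)
        assert max(abs(v) for v in report.values()) == pytest.approx(
            solution.residual_norm, abs=1e-15
        )

    def test_perturbed_edge_flow_imbalances_its_endpoints(self, headline_case):
        case, network, solution, _ = headline_case
        bset = assemble_boundary_set(case.patient, case.simplification)
        delta = 1e-6
        flows = dict(solution.edge_flows)
        flows[("mpv_mid", "shunt_tee")] += delta
        perturbed = dataclasses.replace(solution, edge_flows=flows)
        base = residual_report(network, bset, solution)
        report = residual_report(network, bset, perturbed)
        changed = {
            n: report[n] - base[n]
            for n in report
            if abs(report[n] - base[n]) > delta / 2
        }
        assert changed == {
            "mpv_mid": pytest.approx(-delta),
            "shunt_tee": pytest.approx(delta),
        }

    def test_zero_flow_solution_imbalance_equals_inflow(self, headline_case):
        case, network, solution, _ = headline_case
        bset = assemble_boundary_set(case.patient, case.simplification)
        zero = dataclasses.replace(
            solution, edge_flows={e: 0.0 for e in solution.edge_flows}
        )
        report = residual_report(network, bset, zero)
        assert report["sv_in"] == pytest.approx(bset.q_sv)
        assert report["smv_in"] == pytest.approx(bset.q_smv)

    def test_topology_mismatch_rejected(self, headline_case, patients):
        case, network, solution, _ = headline_case
        other = build_network(
            enumerate_cases([patients[0]])[0]  # LPV position, different edges
        )
        bset = assemble_boundary_set(case.patient, case.simplification)
        with pytest.raises(ValueError):
            residual_report(other, bset, solution)


class TestDegenerateAndDeterminism:
    def test_zero_inflow_returns_zero_solution(self, patients):
        case = enumerate_cases([patients[0]])[0]
        net = build_network(case)
        sol = solve(net, {"q_sv": 0.0, "q_smv": 0.0})
        assert sol.converged and sol.iterations == 0
        assert all(v == 0.0 for v in sol.node_pressures.values())
        assert all(v == 0.0 for v in sol.edge_flows.values())

    def test_inconsistent_boundary_rejected(self, patients):
        case = enumerate_cases([patients[0]])[0]  # Type A: needs q_sv/q_smv
        net = build_network(case)
        with pytest.raises(ValueError):
            solve(net, {"q_total": 7.86e-5})

    def test_bit_identical_re_solve(self, patients):
        case = enumerate_cases([patients[0]])[4]  # MPV position, Type B
        net = build_network(case)
        bset = assemble_boundary_set(case.patient, case.simplification)
        a = solve(net, bset)
        b = solve(net, bset)
        assert a.node_pressures == b.node_pressures
        assert a.edge_flows == b.edge_flows


class TestPhysiologicalTrends:
    def test_mpv_pressure_invariant_across_simplification(self, full_study):
        for patient in ("patient-1", "patient-2"):
            for position in ("LPV", "MPV", "RPV"):
                ppg = [
                    full_study.rows[(patient, position, t)].ppg for t in "ABC"
                ]
                assert max(ppg) - min(ppg) <= 1e-8 * max(ppg)

    def test_wider_shunt_lowers_portal_pressure(self, patients):
        ppg, frac = [], []
        for d in (0.006, 0.008, 0.010):
            case = [
                c
                for c in enumerate_cases(
                    [patients[0]], shunt=ShuntConfig(ShuntPosition.MPV, diameter=d)
                )
                if c.shunt.position is ShuntPosition.MPV
                and c.simplification.label == "A"
            ][0]
            net = build_network(case)
            bset = assemble_boundary_set(case.patient, case.simplification)
            sol = solve(net, bset)
            ppg.append(sol.node_pressures["mpv_mid"])
            frac.append(sol.edge_flows[("shunt_inlet", "ivc")] / bset.q_total)
        assert ppg[0] > ppg[1] > ppg[2]
        assert frac[0] < frac[1] < frac[2]

    def test_shunt_velocity_similar_across_positions(self, full_study):
        for patient in ("patient-1", "patient-2"):
            v = [
                full_study.rows[(patient, pos, "A")].shunt_velocity
                for pos in ("LPV", "MPV", "RPV")
            ]
            assert (max(v) - min(v)) / min(v) < 0.10


class TestSerialization:
    def test_solution_json_round_trip_fields(self, headline_case):
        import json

        _, _, solution, _ = headline_case
        payload = json.loads(solution.to_json())
        assert payload["converged"] is True
        assert payload["node_pressures_pa"]["ivc"] == 0.0
        assert payload["node_pressures_mmhg"]["mpv_mid"] == pytest.approx(
            11.44, abs=0.05
        )
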