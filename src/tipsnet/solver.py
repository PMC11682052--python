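"""Steady nonlinear solver for the portal flow network.

Unknowns are the static pressures of all non-sink nodes and the flows of all
non-prescribed edges. The residual system couples one pressure-drop equation
per edge (friction + minor + area-change losses for segments, ``P = R q`` for
resistance outlets) with mass conservation at every interior node; inflow
edges carry their prescribed boundary flows exactly and the IVC sink is
pinned at zero pressure.

The primary method is a damped Newton iteration with analytic loss
derivatives, started from the all-laminar linear solution. Because every loss
law is strictly monotone in its flow, the tree-plus-shunt topologies built by
:mod:`tipsnet.anatomy` also admit an independent one-dimensional route:
recursively reduce each junction to a scalar flow-split equation and solve it
by bracketed root finding (:func:`solve_path_reduction`). The two routes
agree to solver tolerance and the second doubles as a fallback.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Union

import numpy as np
from scipy.optimize import brentq

from .anatomy import BLOOD, FlowNetwork, FluidProperties
from .boundary import BoundarySet
from .hydraulics import EdgeLossModel, segment_drop
from .units import mmhg_to_pa, pa_to_mmhg

__all__ = [
    "NetworkSolution",
    "ConvergenceError",
    "solve",
    "solve_newton",
    "solve_path_reduction",
    "residual_report",
    "pressure_at",
]

Edge = tuple[str, str]
BoundaryLike = Union[BoundarySet, Mapping[str, float]]

#: Pressure-drop equation tolerance (Pa); mass tolerance is the solve() argument.
EDGE_TOLERANCE = 1e-6


class ConvergenceError(RuntimeError):
    """Raised when the solver fails to converge; carries the residual history."""

    def __init__(self, message: str, residual_history: list[float]):
        super().__init__(message)
        self.residual_history = residual_history


@dataclass
class NetworkSolution:
    """Converged nodal pressures (Pa) and signed edge flows (m^3 s^-1)."""

    node_pressures: dict[str, float]
    edge_flows: dict[Edge, float]
    residual_norm: float
    iterations: int
    converged: bool
    method: str = "newton"
    probes: dict[str, str] = field(default_factory=dict)

    def pressure(self, probe: str, mmhg: bool = False) -> float:
        node = self.probes.get(probe, probe)
        if node not in self.node_pressures:
            raise KeyError(f"unknown probe or node: {probe!r}")
        p = self.node_pressures[node]
        return pa_to_mmhg(p) if mmhg else p

    def to_json(self) -> str:
        """Serialize node pressures (Pa and mmHg), flows and diagnostics."""
        payload = {
            "node_pressures_pa": dict(sorted(self.node_pressures.items())),
            "node_pressures_mmhg": {
                k: pa_to_mmhg(v) for k, v in sorted(self.node_pressures.items())
            },
            "edge_flows": {f"{u}->{v}": q for (u, v), q in sorted(self.edge_flows.items())},
            "residual_norm": self.residual_norm,
            "iterations": self.iterations,
            "converged": self.converged,
            "method": self.method,
        }
        return json.dumps(payload, sort_keys=True)


def _boundary_flows(boundary: BoundaryLike) -> Mapping[str, float]:
    return boundary.flows if isinstance(boundary, BoundarySet) else boundary


def _prescribed_flows(
    network: FlowNetwork, boundary: BoundaryLike
) -> dict[Edge, float]:
    """Map each inflow edge to its prescribed flow; error on inlet mismatch."""
    flows = _boundary_flows(boundary)
    prescribed: dict[Edge, float] = {}
    for node, key in network.inflows.items():
        if key not in flows:
            raise ValueError(f"boundary set lacks inflow {key!r} for node {node!r}")
        (edge,) = network.graph.out_edges(node)
        prescribed[edge] = flows[key]
    return prescribed


def _edge_law(data: dict, q: float, fluid: FluidProperties, model: EdgeLossModel):
    """(pressure drop, d drop / d q) for one edge at signed flow q."""
    if "resistance" in data:
        r = data["resistance"]
        return r * q, r
    return segment_drop(data["segment"], q, fluid, model)


def _edge_linear_resistance(data: dict, fluid: FluidProperties) -> float:
    """Laminar (linearized) resistance used for the initial guess."""
    if "resistance" in data:
        return data["resistance"]
    _, deriv = segment_drop(data["segment"], 0.0, fluid)
    return max(deriv, 1e-6)  # floor keeps zero-length stubs solvable


def solve_newton(
    network: FlowNetwork,
    boundary: BoundaryLike,
    fluid: FluidProperties = BLOOD,
    model: EdgeLossModel = EdgeLossModel(),
    tolerance: float = 1e-12,
    max_iter: int = 200,
) -> NetworkSolution:
    """Damped Newton iteration on nodal pressures and free edge flows."""
    g = network.graph
    sink = network.sink
    prescribed = _prescribed_flows(network, boundary)
    q_total = sum(prescribed.values())

    nodes = sorted(n for n in g.nodes if n != sink)
    edges = sorted(g.edges)
    free_edges = [e for e in edges if e not in prescribed]
    interior = [n for n in nodes if n not in network.inflows]
    idx_p = {n: i for i, n in enumerate(nodes)}
    idx_q = {e: len(nodes) + i for i, e in enumerate(free_edges)}
    n_unknown = len(nodes) + len(free_edges)

    def finish(x: np.ndarray, iterations: int, converged: bool, residual: float):
        pressures = {sink: 0.0}
        pressures.update({n: float(x[idx_p[n]]) for n in nodes})
        flows = dict(prescribed)
        flows.update({e: float(x[idx_q[e]]) for e in free_edges})
        return NetworkSolution(
            node_pressures=pressures,
            edge_flows=flows,
            residual_norm=residual,
            iterations=iterations,
            converged=converged,
            probes=dict(network.probes),
        )

    if q_total == 0.0 and all(v == 0.0 for v in prescribed.values()):
        return finish(np.zeros(n_unknown), 0, True, 0.0)

    p_scale = mmhg_to_pa(25.0)
    q_scale = max(abs(q_total), 1e-10)

    # Initial guess: all-laminar linear network (conductance form).
    x = np.zeros(n_unknown)
    lin_r = {e: _edge_linear_resistance(g.edges[e], fluid) for e in edges}
    m = len(interior)
    if m:
        y = np.zeros((m, m))
        b = np.zeros(m)
        row = {n: i for i, n in enumerate(interior)}
        for (u, v), r in lin_r.items():
            if (u, v) in prescribed:
                if v in row:
                    b[row[v]] += prescribed[(u, v)]
                continue
            cond = 1.0 / r
            for a, sgn in ((u, 1.0), (v, 1.0)):
                if a in row:
                    y[row[a], row[a]] += cond
            if u in row and v in row:
                y[row[u], row[v]] -= cond
                y[row[v], row[u]] -= cond
        p_lin = np.linalg.solve(y, b)
        p_map = {n: p_lin[i] for n, i in row.items()}
    else:
        p_map = {}
    p_map[sink] = 0.0
    for e in free_edges:
        u, v = e
        x[idx_q[e]] = (p_map.get(u, 0.0) - p_map.get(v, 0.0)) / lin_r[e]
    for n in nodes:
        if n in p_map:
            x[idx_p[n]] = p_map[n]
    # Inflow node pressures from their edge law at the prescribed flow.
    for (u, v), q in prescribed.items():
        drop, _ = _edge_law(g.edges[(u, v)], q, fluid, model)
        x[idx_p[u]] = (p_map.get(v, 0.0)) + drop

    def residuals(xv: np.ndarray):
        f = np.zeros(len(edges) + len(interior))
        jac = np.zeros((len(edges) + len(interior), n_unknown))
        for i, e in enumerate(edges):
            u, v = e
            q = prescribed[e] if e in prescribed else xv[idx_q[e]]
            drop, ddrop = _edge_law(g.edges[e], q, fluid, model)
            pu = xv[idx_p[u]] if u != sink else 0.0
            pv = xv[idx_p[v]] if v != sink else 0.0
            f[i] = pu - pv - drop
            if u != sink:
                jac[i, idx_p[u]] = 1.0
            if v != sink:
                jac[i, idx_p[v]] = -1.0
            if e in idx_q:
                jac[i, idx_q[e]] = -ddrop
        for j, n in enumerate(interior):
            r = len(edges) + j
            acc = 0.0
            for e in g.in_edges(n):
                q = prescribed[e] if e in prescribed else xv[idx_q[e]]
                acc += q
                if e in idx_q:
                    jac[r, idx_q[e]] += 1.0
            for e in g.out_edges(n):
                q = prescribed[e] if e in prescribed else xv[idx_q[e]]
                acc -= q
                if e in idx_q:
                    jac[r, idx_q[e]] -= 1.0
            f[r] = acc
        return f, jac

    d_row = np.concatenate(
        [np.full(len(edges), 1.0 / p_scale), np.full(len(interior), 1.0 / q_scale)]
    )
    d_col = np.concatenate(
        [np.full(len(nodes), p_scale), np.full(len(free_edges), q_scale)]
    )

    history: list[float] = []
    iterations = 0
    for iterations in range(1, max_iter + 1):
        f, jac = residuals(x)
        mass_max = float(np.max(np.abs(f[len(edges):]))) if interior else 0.0
        edge_max = float(np.max(np.abs(f[: len(edges)])))
        history.append(mass_max)
        if mass_max <= tolerance and edge_max <= EDGE_TOLERANCE:
            return finish(x, iterations - 1, True, mass_max)
        fs = d_row * f
        js = jac * d_row[:, None] * d_col[None, :]
        try:
            dy = np.linalg.solve(js, -fs)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular Jacobian: {exc}", history) from exc
        dx = d_col * dy
        phi0 = float(np.linalg.norm(fs))
        lam = 1.0
        for _ in range(40):
            f_new, _ = residuals(x + lam * dx)
            if float(np.linalg.norm(d_row * f_new)) < phi0 * (1.0 - 1e-4 * lam):
                break
            lam *= 0.5
        x = x + lam * dx

    f, _ = residuals(x)
    mass_max = float(np.max(np.abs(f[len(edges):]))) if interior else 0.0
    raise ConvergenceError(
        f"Newton failed to converge in {max_iter} iterations "
        f"(mass residual {mass_max:.3e} m^3/s)",
        history,
    )


def solve_path_reduction(
    network: FlowNetwork,
    boundary: BoundaryLike,
    fluid: FluidProperties = BLOOD,
    model: EdgeLossModel = EdgeLossModel(),
) -> NetworkSolution:
    """Reference route: recursive reduction to scalar flow-split equations.

    Valid for networks where, downstream of the inflow junction, every node
    has at most two outgoing edges and all paths end at the sink (the
    tree-plus-shunt topologies of the study). Each two-way junction is
    reduced to a single bracketed root-finding problem on the flow split; the
    required upstream pressure of each subtree is strictly increasing in its
    flow, so the split is unique.
    """
    g = network.graph
    sink = network.sink
    prescribed = _prescribed_flows(network, boundary)
    q_total = sum(prescribed.values())

    def edge_drop(e: Edge, q: float) -> float:
        return _edge_law(g.edges[e], q, fluid, model)[0]

    def required(node: str, q: float) -> float:
        """Pressure needed at `node` to discharge flow q to the sink."""
        if node == sink:
            return 0.0
        out = sorted(g.out_edges(node))
        if len(out) == 1:
            (e,) = out
            return edge_drop(e, q) + required(e[1], q)
        if len(out) != 2:
            raise ValueError(f"path reduction needs out-degree <= 2 at {node!r}")
        e1, e2 = out
        if q == 0.0:
            return 0.0

        def imbalance(q1: float) -> float:
            p1 = edge_drop(e1, q1) + required(e1[1], q1)
            p2 = edge_drop(e2, q - q1) + required(e2[1], q - q1)
            return p1 - p2

        q1 = brentq(imbalance, 0.0, q, xtol=1e-24, rtol=8.9e-16)
        return edge_drop(e1, q1) + required(e1[1], q1)

    pressures: dict[str, float] = {sink: 0.0}
    flows: dict[Edge, float] = dict(prescribed)

    def descend(node: str, q: float, p: float) -> None:
        pressures[node] = p
        if node == sink:
            pressures[node] = 0.0
            return
        out = sorted(g.out_edges(node))
        if len(out) == 1:
            (e,) = out
            flows[e] = q
            descend(e[1], q, p - edge_drop(e, q))
            return
        e1, e2 = out
        if q == 0.0:
            q1 = 0.0
        else:

            def imbalance(q1: float) -> float:
                pa = edge_drop(e1, q1) + required(e1[1], q1)
                pb = edge_drop(e2, q - q1) + required(e2[1], q - q1)
                return pa - pb

            q1 = brentq(imbalance, 0.0, q, xtol=1e-24, rtol=8.9e-16)
        flows[e1], flows[e2] = q1, q - q1
        descend(e1[1], q1, p - edge_drop(e1, q1))
        descend(e2[1], q - q1, p - edge_drop(e2, q - q1))

    # Entry junction: the (unique) node fed by all inflow edges.
    targets = {e[1] for e in prescribed}
    if len(targets) != 1:
        raise ValueError("path reduction expects a single inflow junction")
    (entry,) = targets
    p_entry = required(entry, q_total)
    descend(entry, q_total, p_entry)
    for (u, v), q in prescribed.items():
        pressures[u] = pressures[v] + edge_drop((u, v), q)

    solution = NetworkSolution(
        node_pressures=pressures,
        edge_flows=flows,
        residual_norm=0.0,
        iterations=0,
        converged=True,
        method="path-reduction",
        probes=dict(network.probes),
    )
    solution.residual_norm = max(
        abs(v) for v in residual_report(network, boundary, solution).values()
    )
    return solution


def solve(
    network: FlowNetwork,
    boundary: BoundaryLike,
    fluid: FluidProperties = BLOOD,
    model: EdgeLossModel = EdgeLossModel(),
    tolerance: float = 1e-12,
    max_iter: int = 200,
) -> NetworkSolution:
    """Solve the network; damped Newton with path-reduction fallback."""
    try:
        return solve_newton(network, boundary, fluid, model, tolerance, max_iter)
    except ConvergenceError:
        return solve_path_reduction(network, boundary, fluid, model)


def residual_report(
    network: FlowNetwork, boundary: BoundaryLike, solution: NetworkSolution
) -> dict[str, float]:
    """Recompute per-node mass imbalance (m^3/s) from the solution flows.

    Inflow nodes receive their prescribed boundary flow as an external
    injection; the sink is excluded. For a converged solution the maximum
    absolute imbalance equals the solution's residual norm.
    """
    g = network.graph
    if set(solution.edge_flows) != set(g.edges):
        raise ValueError("solution edges do not match the network topology")
    flows = _boundary_flows(boundary)
    report: dict[str, float] = {}
    for node in sorted(g.nodes):
        if node == network.sink:
            continue
        acc = 0.0
        if node in network.inflows:
            acc += flows[network.inflows[node]]
        for e in g.in_edges(node):
            acc += solution.edge_flows[e]
        for e in g.out_edges(node):
            acc -= solution.edge_flows[e]
        report[node] = acc
    return report


def pressure_at(solution: NetworkSolution, probe: str, mmhg: bool = False) -> float:
    """Nodal static pressure at a probe (Pa, or mmHg when requested)."""
    return solution.pressure(probe, mmhg=mmhg)
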