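"""Minimum-node fire-safe evacuation routing on a time-dependent road graph.

A token departs a source junction and moves along directed edges; traversal
times follow the traffic-dependent edge travel times.  A binary availability
function ``rho(node, t)`` derived from the fire arrival-time field marks a
junction unavailable from the instant the fire reaches it.  The objective is
the path visiting the FEWEST junctions whose every junction is still
available at the token's visit time; total travel time and then accumulated
traffic intensity break ties, making the returned plan unique.

``find_opera`` is a multi-criteria label-setting search; ``brute_force_opera``
enumerates all simple paths and serves as its independent reference
semantics on small graphs.  Infeasibility is a first-class result (an
EvacuationPlan with ``feasible=False``), never an exception.
"""

from __future__ import annotations

import heapq
import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from firevac.raster import Raster
from firevac.roads import RoadGraph, edge_travel_time

__all__ = [
    "AvailabilityFunction",
    "EvacuationPlan",
    "rho",
    "find_opera",
    "brute_force_opera",
    "validate_plan",
    "plan_to_geojson",
    "write_plan",
    "RoutingError",
]


class RoutingError(ValueError):
    """Raised on routing contract violations (bad nodes, out-of-range times)."""


@dataclass
class AvailabilityFunction:
    """Binary node availability over time, backed by a fire arrival raster.

    A junction is unavailable at time ``t`` (rho = 0) iff the fire arrival
    time of any raster cell within ``safety_margin`` metres of the junction
    is <= ``t``.  Junctions outside the raster extent are never burned.
    ``horizon`` is the final simulated minute; rho is only defined on
    [0, horizon].  ``arrival=None`` models the no-fire case (rho == 1).
    """

    arrival: Raster | None
    safety_margin: float = 0.0
    horizon: float = 60.0

    def __post_init__(self) -> None:
        if not self.horizon > 0:
            raise RoutingError("horizon must be > 0")
        if self.safety_margin < 0:
            raise RoutingError("safety_margin must be >= 0")

    def earliest_arrival_near(self, x: float, y: float) -> float:
        """Earliest fire arrival (minutes) within safety_margin of a point; inf if never."""
        if self.arrival is None:
            return math.inf
        r = self.arrival
        if self.safety_margin == 0.0:
            idx = r.index_of(x, y)
            if idx is None:
                return math.inf
            v = r.values[idx]
            return math.inf if v == r.nodata else float(v)
        x0, y0 = r.origin
        m = self.safety_margin
        col_lo = max(0, int(math.floor((x - m - x0) / r.cell_size)))
        col_hi = min(r.ncols - 1, int(math.floor((x + m - x0) / r.cell_size)))
        row_lo = max(0, int(math.floor((y0 - (y + m)) / r.cell_size)))
        row_hi = min(r.nrows - 1, int(math.floor((y0 - (y - m)) / r.cell_size)))
        if col_lo > col_hi or row_lo > row_hi:
            return math.inf
        block = r.values[row_lo:row_hi + 1, col_lo:col_hi + 1]
        X, Y = np.meshgrid(
            x0 + (np.arange(col_lo, col_hi + 1) + 0.5) * r.cell_size,
            y0 - (np.arange(row_lo, row_hi + 1) + 0.5) * r.cell_size,
        )
        near = (X - x) ** 2 + (Y - y) ** 2 <= m * m
        vals = block[near & (block != r.nodata)]
        return float(vals.min()) if vals.size else math.inf

    def scaled(self, lam: float) -> "AvailabilityFunction":
        """Availability with every arrival time multiplied by ``lam`` (delayed fire)."""
        if self.arrival is None or math.isinf(lam):
            return AvailabilityFunction(None, self.safety_margin, self.horizon)
        vals = self.arrival.values.copy()
        mask = vals != self.arrival.nodata
        vals[mask] = vals[mask] * lam
        return AvailabilityFunction(self.arrival.copy_with(vals), self.safety_margin, self.horizon)


def rho(node_xy: tuple[float, float], t: float, avail: AvailabilityFunction) -> int:
    """Binary availability: 0 iff the fire reached the junction by time ``t``."""
    if t < 0 or t > avail.horizon:
        raise RoutingError(f"time {t} outside [0, {avail.horizon}]")
    return 0 if avail.earliest_arrival_near(*node_xy) <= t else 1


@dataclass
class EvacuationPlan:
    """An evacuation route with visit times and its node-count objective value.

    ``opera_value`` is the number of junctions on the route (the quantity
    being minimized); ``rejected_nodes`` lists junctions the search had to
    discard because the fire would reach them before the token.
    """

    nodes: list[str]
    visit_times: list[float]
    feasible: bool
    opera_value: int = 0
    total_travel_min: float = 0.0
    total_phi: float = 0.0
    rejected_nodes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.feasible:
            if len(self.nodes) != len(self.visit_times):
                raise RoutingError("one visit time per node required")
            if self.opera_value == 0:
                self.opera_value = len(self.nodes)
            if self.opera_value != len(self.nodes):
                raise RoutingError("opera_value must equal the node count")
            if any(b < a - 1e-9 for a, b in zip(self.visit_times, self.visit_times[1:])):
                raise RoutingError("visit times must be non-decreasing")

    @classmethod
    def infeasible(cls, rejected: Sequence[str] = ()) -> "EvacuationPlan":
        return cls(nodes=[], visit_times=[], feasible=False, opera_value=0,
                   rejected_nodes=sorted(set(rejected)))

    def summary(self) -> dict:
        return {
            "opera_value": self.opera_value,
            "feasible": self.feasible,
            "total_travel_min": self.total_travel_min,
            "total_phi": self.total_phi,
            "nodes": list(self.nodes),
            "visit_times_min": list(self.visit_times),
            "rejected_nodes": list(self.rejected_nodes),
        }


def _path_key(plan_nodes: tuple[str, ...], time: float, phi: float) -> tuple:
    # total order: node count, travel time, accumulated phi, then node ids
    return (len(plan_nodes), time, phi, plan_nodes)


def _check_endpoints(graph: RoadGraph, source: str, sink: str) -> None:
    if source not in graph.nodes:
        raise RoutingError(f"source {source!r} not in graph")
    if sink not in graph.nodes:
        raise RoutingError(f"sink {sink!r} not in graph")
    if source == sink:
        raise RoutingError("source and sink must differ")


def find_opera(graph: RoadGraph, avail: AvailabilityFunction, source: str, sink: str,
               depart: float = 0.0) -> EvacuationPlan:
    """Label-setting search for the minimum-node fire-safe route.

    Labels carry (node, visit time, node count, accumulated phi, path); a
    label is dominated when another label at the same node is no worse in
    time, count and phi.  Labels are settled in the total tie-break order
    (count, time, phi, node ids), so the first settled sink label is the
    unique optimum.  Returns an infeasible plan (never raises) when no safe
    path exists within the horizon.
    """
    _check_endpoints(graph, source, sink)
    if depart < 0 or depart > avail.horizon:
        raise RoutingError(f"departure time {depart} outside [0, {avail.horizon}]")
    rejected: set[str] = set()
    if rho(graph.nodes[source], depart, avail) == 0:
        return EvacuationPlan.infeasible(rejected=[source])

    start = (source,)
    counter = itertools.count()
    heap: list[tuple[tuple, int, str, float, float, tuple[str, ...]]] = [
        (_path_key(start, depart, 0.0), next(counter), source, depart, 0.0, start)
    ]
    # pareto frontier per node over (time, count, phi)
    frontier: dict[str, list[tuple[float, int, float]]] = {}

    def dominated(node: str, time: float, count: int, phi: float) -> bool:
        return any(
            t0 <= time + 1e-12 and c0 <= count and p0 <= phi + 1e-12
            for (t0, c0, p0) in frontier.get(node, ())
        )

    while heap:
        key, _, node, time, phi, path = heapq.heappop(heap)
        count = len(path)
        if dominated(node, time, count, phi):
            continue
        frontier.setdefault(node, []).append((time, count, phi))
        if node == sink:
            times = _visit_times(graph, path, depart)
            return EvacuationPlan(
                nodes=list(path),
                visit_times=times,
                feasible=True,
                opera_value=len(path),
                total_travel_min=times[-1] - depart,
                total_phi=phi,
                rejected_nodes=sorted(rejected),
            )
        for succ in graph.successors(node):
            if succ in path:
                continue  # simple paths only
            edge = graph.edge(node, succ)
            t_next = time + edge_travel_time(edge)
            if t_next > avail.horizon:
                continue
            if rho(graph.nodes[succ], t_next, avail) == 0:
                rejected.add(succ)
                continue
            phi_next = phi + edge.phi
            path_next = path + (succ,)
            if dominated(succ, t_next, len(path_next), phi_next):
                continue
            heapq.heappush(
                heap,
                (_path_key(path_next, t_next, phi_next), next(counter),
                 succ, t_next, phi_next, path_next),
            )
    return EvacuationPlan.infeasible(rejected=sorted(rejected))


def _visit_times(graph: RoadGraph, path: Sequence[str], depart: float) -> list[float]:
    times = [depart]
    for u, v in zip(path, path[1:]):
        times.append(times[-1] + edge_travel_time(graph.edge(u, v)))
    return times


def brute_force_opera(graph: RoadGraph, avail: AvailabilityFunction, source: str, sink: str,
                      depart: float = 0.0, max_nodes: int = 12) -> EvacuationPlan:
    """Exhaustive-enumeration reference for :func:`find_opera` on small graphs.

    Enumerates every simple source->sink path, applies the identical
    feasibility rules (safe nodes at visit times, horizon bound) and the
    identical (count, time, phi, node-id) tie-break.
    """
    _check_endpoints(graph, source, sink)
    if len(graph.nodes) > max_nodes:
        raise RoutingError(f"graph too large for enumeration (> {max_nodes} nodes)")
    if depart < 0 or depart > avail.horizon:
        raise RoutingError(f"departure time {depart} outside [0, {avail.horizon}]")
    rejected: set[str] = set()
    if rho(graph.nodes[source], depart, avail) == 0:
        return EvacuationPlan.infeasible(rejected=[source])

    import networkx as nx

    g = graph.to_networkx()
    best: tuple | None = None
    best_plan: EvacuationPlan | None = None
    for path in nx.all_simple_paths(g, source, sink):
        times = _visit_times(graph, path, depart)
        ok = True
        for node, t in zip(path, times):
            if t > avail.horizon:
                ok = False
                break
            if rho(graph.nodes[node], t, avail) == 0:
                rejected.add(node)
                ok = False
                break
        if not ok:
            continue
        phi = sum(graph.edge(u, v).phi for u, v in zip(path, path[1:]))
        key = _path_key(tuple(path), times[-1], phi)
        if best is None or key < best:
            best = key
            best_plan = EvacuationPlan(
                nodes=list(path),
                visit_times=times,
                feasible=True,
                opera_value=len(path),
                total_travel_min=times[-1] - depart,
                total_phi=phi,
            )
    if best_plan is None:
        return EvacuationPlan.infeasible(rejected=sorted(rejected))
    best_plan.rejected_nodes = sorted(rejected)
    return best_plan


def validate_plan(plan: EvacuationPlan, graph: RoadGraph, avail: AvailabilityFunction,
                  tol: float = 1e-6) -> list[str]:
    """Return the list of contract violations of a plan (empty iff valid).

    Checks: consecutive nodes are graph edges ("connectivity"), visit times
    match the edge travel times ("timing"), every node is available at its
    visit time ("safety"), and times stay within the horizon ("horizon").
    """
    violations: list[str] = []
    if not plan.feasible:
        return violations
    for node in plan.nodes:
        if node not in graph.nodes:
            violations.append(f"connectivity: node {node!r} not in graph")
    for u, v in zip(plan.nodes, plan.nodes[1:]):
        if not graph.has_edge(u, v):
            violations.append(f"connectivity: no edge {u}->{v}")
    if len(plan.visit_times) == len(plan.nodes):
        for i, (u, v) in enumerate(zip(plan.nodes, plan.nodes[1:])):
            if not graph.has_edge(u, v):
                continue
            expected = plan.visit_times[i] + edge_travel_time(graph.edge(u, v))
            if abs(plan.visit_times[i + 1] - expected) > tol:
                violations.append(
                    f"timing: visit time at {v} is {plan.visit_times[i + 1]:.6f}, "
                    f"expected {expected:.6f}"
                )
    else:
        violations.append("timing: one visit time per node required")
    for node, t in zip(plan.nodes, plan.visit_times):
        if node not in graph.nodes:
            continue
        if t > avail.horizon:
            violations.append(f"horizon: {node} visited at {t:.3f} > {avail.horizon}")
            continue
        if t >= 0 and rho(graph.nodes[node], t, avail) == 0:
            violations.append(f"safety: node {node} burned by visit time {t:.3f}")
    return violations


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def plan_to_geojson(plan: EvacuationPlan, graph: RoadGraph) -> dict:
    """Plan as a GeoJSON LineString plus rejected-node Points."""
    features = []
    if plan.feasible and len(plan.nodes) >= 2:
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [list(graph.nodes[n]) for n in plan.nodes],
                },
                "properties": {
                    "kind": "evacuation_route",
                    "opera_value": plan.opera_value,
                    "nodes": list(plan.nodes),
                    "t_min": list(plan.visit_times),
                },
            }
        )
    for node in plan.rejected_nodes:
        if node in graph.nodes:
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": list(graph.nodes[node])},
                    "properties": {"kind": "rejected_node", "id": node},
                }
            )
    return {"type": "FeatureCollection", "features": features}


def write_plan(plan: EvacuationPlan, graph: RoadGraph, geojson_path: str | Path,
               summary_path: str | Path | None = None) -> Path:
    geojson_path = Path(geojson_path)
    geojson_path.write_text(json.dumps(plan_to_geojson(plan, graph), sort_keys=True) + "\n")
    if summary_path is not None:
        Path(summary_path).write_text(json.dumps(plan.summary(), sort_keys=True) + "\n")
    return geojson_path
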