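"""Oriented road graph and traffic-flow speed statistics.

The road network is an oriented graph whose edges carry a length (m), a
normalized traffic-intensity weight ``phi`` in [0, 1] and a free-flow speed
``v_free`` (m/h).  Traffic intensity maps to an expected traversal speed by
a Greenshields-style linear degradation ``v = v_free * (1 - phi)``, floored
at ``PHI_SPEED_FLOOR * v_free`` so that saturated edges stay traversable.

Speed samples (per-vehicle speeds over a period or segment) are summarized
by the classical descriptors: time-mean (arithmetic) speed, space-mean
(harmonic) speed, the 85th-percentile speed and the modal speed interval.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path


import networkx as nx
import numpy as np

__all__ = [
    "RoadGraph",
    "RoadEdge",
    "SpeedSample",
    "SpeedSummary",
    "time_mean_speed",
    "space_mean_speed",
    "s85",
    "v_mod",
    "summarize_speeds",
    "edge_travel_time",
    "read_road_graph",
    "write_road_graph",
    "read_speed_sample",
    "RoadGraphError",
    "PHI_SPEED_FLOOR",
]

#: Fraction of free-flow speed retained on a fully saturated edge (phi = 1),
#: preventing division blow-up in travel times.
PHI_SPEED_FLOOR = 0.05


class RoadGraphError(ValueError):
    """Raised on road-graph contract violations."""


@dataclass(frozen=True)
class RoadEdge:
    """A directed road segment between two junctions."""

    from_id: str
    to_id: str
    length: float
    phi: float
    v_free: float

    def __post_init__(self) -> None:
        if not self.length > 0:
            raise RoadGraphError(f"edge {self.from_id}->{self.to_id}: length must be > 0")
        if not 0.0 <= self.phi <= 1.0:
            raise RoadGraphError(f"edge {self.from_id}->{self.to_id}: phi must be in [0, 1]")
        if not self.v_free > 0:
            raise RoadGraphError(f"edge {self.from_id}->{self.to_id}: v_free must be > 0")


@dataclass
class RoadGraph:
    """Oriented graph of road junctions and directed road segments.

    ``nodes`` maps junction id to its (x, y) coordinates in projected
    metres; ``edges`` is keyed by (from_id, to_id).
    """

    nodes: dict[str, tuple[float, float]]
    edges: dict[tuple[str, str], RoadEdge] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (u, v), edge in self.edges.items():
            if u not in self.nodes or v not in self.nodes:
                raise RoadGraphError(f"edge {u}->{v} references a missing node")
            if (edge.from_id, edge.to_id) != (u, v):
                raise RoadGraphError(f"edge key {(u, v)} disagrees with edge ids")

    def add_edge(self, edge: RoadEdge) -> None:
        if edge.from_id not in self.nodes or edge.to_id not in self.nodes:
            raise RoadGraphError(f"edge {edge.from_id}->{edge.to_id} references a missing node")
        self.edges[(edge.from_id, edge.to_id)] = edge

    def successors(self, node_id: str) -> list[str]:
        return sorted(v for (u, v) in self.edges if u == node_id)

    def edge(self, u: str, v: str) -> RoadEdge:
        try:
            return self.edges[(u, v)]
        except KeyError:
            raise RoadGraphError(f"no edge {u}->{v}") from None

    def has_edge(self, u: str, v: str) -> bool:
        return (u, v) in self.edges

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for nid, (x, y) in self.nodes.items():
            g.add_node(nid, x=x, y=y)
        for (u, v), e in self.edges.items():
            g.add_edge(u, v, length=e.length, phi=e.phi, v_free=e.v_free,
                       travel_min=edge_travel_time(e))
        return g

    def __len__(self) -> int:
        return len(self.nodes)


# ---------------------------------------------------------------------------
# Speed statistics
# ---------------------------------------------------------------------------

@dataclass
class SpeedSample:
    """Per-vehicle speeds (m/h, all > 0) observed on a segment or period."""

    speeds: list[float]
    segment_length: float | None = None

    def __post_init__(self) -> None:
        if not self.speeds:
            raise RoadGraphError("speed sample must be non-empty")
        if any(s <= 0 for s in self.speeds):
            raise RoadGraphError("all speeds must be > 0")
        if self.segment_length is not None and not self.segment_length > 0:
            raise RoadGraphError("segment_length must be > 0 when given")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.speeds, dtype=float)


@dataclass(frozen=True)
class SpeedSummary:
    """The four speed descriptors of a sample (all m/h)."""

    time_mean: float
    space_mean: float
    s85: float
    v_mod: float


def time_mean_speed(sample: SpeedSample) -> float:
    """Arithmetic mean speed over the vehicles of the sample."""
    return float(np.mean(sample.as_array()))


def space_mean_speed(sample: SpeedSample) -> float:
    """Harmonic mean speed: n / sum(1/S_i).

    Equivalently the common segment length divided by the mean traversal
    time; never exceeds the time-mean speed.
    """
    s = sample.as_array()
    return float(1.0 / np.mean(1.0 / s))


def s85(sample: SpeedSample) -> float:
    """85th-percentile speed by the nearest-rank rule.

    The returned order statistic is exceeded by at most 15 % of the sample.
    """
    s = np.sort(sample.as_array())
    rank = math.ceil(0.85 * len(s))  # 1-based nearest rank
    return float(s[rank - 1])


def v_mod(sample: SpeedSample, bin_width: float = 5000.0) -> float:
    """Midpoint of the most frequent speed interval (ties -> lower bin).

    Bins are ``[k*w, (k+1)*w)`` anchored at zero with width ``w``.
    """
    if not bin_width > 0:
        raise RoadGraphError("bin_width must be > 0")
    s = sample.as_array()
    idx = np.floor(s / bin_width).astype(int)
    counts = np.bincount(idx)
    best = int(np.argmax(counts))  # argmax takes the first (lowest) maximum
    return float((best + 0.5) * bin_width)


def summarize_speeds(sample: SpeedSample, bin_width: float = 5000.0) -> SpeedSummary:
    return SpeedSummary(
        time_mean=time_mean_speed(sample),
        space_mean=space_mean_speed(sample),
        s85=s85(sample),
        v_mod=v_mod(sample, bin_width),
    )


# ---------------------------------------------------------------------------
# Travel time
# ---------------------------------------------------------------------------

def edge_travel_time(edge: RoadEdge) -> float:
    """Expected traversal time of an edge in minutes.

    ``60 * length / (v_free * max(1 - phi, PHI_SPEED_FLOOR))`` — linear
    speed degradation in phi with a floor keeping the result finite.
    """
    v = edge.v_free * max(1.0 - edge.phi, PHI_SPEED_FLOOR)
    return 60.0 * edge.length / v


# ---------------------------------------------------------------------------
# I/O: GeoJSON graph + nodes CSV + speed-sample CSV
# ---------------------------------------------------------------------------

def write_road_graph(graph: RoadGraph, path: str | Path, nodes_csv: str | Path | None = None) -> Path:
    """Write the graph as GeoJSON LineStrings (and optionally a nodes CSV)."""
    path = Path(path)
    features = []
    for (u, v) in sorted(graph.edges):
        e = graph.edges[(u, v)]
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [list(graph.nodes[u]), list(graph.nodes[v])],
                },
                "properties": {
                    "from": u,
                    "to": v,
                    "length": e.length,
                    "phi": e.phi,
                    "v_free": e.v_free,
                },
            }
        )
    doc = {
        "type": "FeatureCollection",
        "features": features,
        "nodes": {nid: list(xy) for nid, xy in sorted(graph.nodes.items())},
    }
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    if nodes_csv is not None:
        with open(nodes_csv, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "x", "y"])
            for nid in sorted(graph.nodes):
                x, y = graph.nodes[nid]
                writer.writerow([nid, repr(float(x)), repr(float(y))])
    return path


def read_road_graph(path: str | Path) -> RoadGraph:
    """Read a graph written by :func:`write_road_graph` (exact round trip)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"road graph file not found: {path}")
    doc = json.loads(path.read_text())
    nodes: dict[str, tuple[float, float]] = {
        nid: (float(xy[0]), float(xy[1])) for nid, xy in (doc.get("nodes") or {}).items()
    }
    graph = RoadGraph(nodes=nodes)
    for feat in doc.get("features", []):
        props = feat.get("properties") or {}
        u, v = str(props["from"]), str(props["to"])
        if u not in graph.nodes or v not in graph.nodes:
            # tolerate files without the top-level node table
            coords = feat["geometry"]["coordinates"]
            graph.nodes.setdefault(u, (float(coords[0][0]), float(coords[0][1])))
            graph.nodes.setdefault(v, (float(coords[-1][0]), float(coords[-1][1])))
        graph.add_edge(
            RoadEdge(
                from_id=u,
                to_id=v,
                length=float(props["length"]),
                phi=float(props["phi"]),
                v_free=float(props["v_free"]),
            )
        )
    return graph


def read_speed_sample(path: str | Path, segment_length: float | None = None) -> SpeedSample:
    """Read a single-column CSV of per-vehicle speeds (header optional)."""
    path = Path(path)
    speeds: list[float] = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row:
                continue
            try:
                speeds.append(float(row[0]))
            except ValueError:
                continue  # header line
    return SpeedSample(speeds=speeds, segment_length=segment_length)
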