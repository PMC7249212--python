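"""Shared test fixtures: all inputs are generated programmatically."""

from __future__ import annotations

import math

import numpy as np
import pytest

from firevac.fixtures import FixtureSpec, make_landscape
from firevac.fire import RosParameters
from firevac.raster import PointSet, Raster, WindField
from firevac.roads import RoadEdge, RoadGraph
from firevac.routing import AvailabilityFunction


@pytest.fixture
def flat_landscape():
    """Flat DEM, uniform fuel class 9, zero humidity, no wind."""
    spec = FixtureSpec(dem_style="flat", fuel_style="uniform",
                       uniform_fuel_class=9, humidity=0.0)
    dem, fuel, hum, winds = make_landscape(spec)
    return dem, fuel, hum, WindField(0.0, 0.0)


@pytest.fixture
def no_damping_params():
    return RosParameters(humidity_damping=0.0)


def make_chain_graph(n: int = 3, length: float = 1000.0, v_free: float = 60000.0,
                     phi: float = 0.0) -> RoadGraph:
    # offset into the default arrival-raster extent so nodes burn when targeted
    nodes = {f"n{i}": (100.0 + float(i) * length, 1000.0) for i in range(n)}
    g = RoadGraph(nodes=nodes)
    for i in range(n - 1):
        g.add_edge(RoadEdge(f"n{i}", f"n{i+1}", length=length, phi=phi, v_free=v_free))
    return g


def make_diamond_graph(short_len: float = 1000.0, long_len: float = 2000.0,
                       v_free: float = 60000.0) -> RoadGraph:
    """Canonical 4-node two-route fixture: A->B->D (short) vs A->C->D (long)."""
    g = RoadGraph(nodes={"A": (0.0, 0.0), "B": (short_len, 500.0),
                         "C": (short_len, -1500.0), "D": (2 * short_len, 0.0)})
    g.add_edge(RoadEdge("A", "B", length=short_len, phi=0.1, v_free=v_free))
    g.add_edge(RoadEdge("B", "D", length=short_len, phi=0.1, v_free=v_free))
    g.add_edge(RoadEdge("A", "C", length=long_len, phi=0.1, v_free=v_free))
    g.add_edge(RoadEdge("C", "D", length=long_len, phi=0.1, v_free=v_free))
    return g


def arrival_raster_burning(points_times: dict[tuple[float, float], float],
                           origin=(0.0, 2000.0), shape=(20, 20), cell_size=100.0) -> Raster:
    """Arrival raster that is nodata everywhere except the cells of given points."""
    vals = np.full(shape, -9999.0)
    r = Raster(values=vals, origin=origin, cell_size=cell_size, nodata=-9999.0)
    for (x, y), t in points_times.items():
        idx = r.index_of(x, y)
        assert idx is not None, f"point ({x}, {y}) outside raster"
        r.values[idx] = t
    return r


def random_routing_instance(seed: int):
    """Random directed graph (<= 10 nodes), arrival field and endpoints."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 11))
    nodes = {f"n{i}": (float(rng.uniform(0, 2000)), float(rng.uniform(0, 2000)))
             for i in range(n)}
    g = RoadGraph(nodes=nodes)
    ids = list(nodes)
    for u in ids:
        for v in ids:
            if u != v and rng.random() < 0.3:
                (x1, y1), (x2, y2) = nodes[u], nodes[v]
                length = max(1.0, math.hypot(x2 - x1, y2 - y1))
                g.add_edge(RoadEdge(u, v, length=length, phi=float(rng.uniform(0, 1)),
                                    v_free=30000.0))
    vals = rng.uniform(0, 40, size=(20, 20))
    vals[rng.random((20, 20)) < 0.5] = -9999.0
    arrival = Raster(values=vals, origin=(0.0, 2000.0), cell_size=100.0, nodata=-9999.0)
    avail = AvailabilityFunction(arrival=arrival, horizon=60.0)
    return g, avail, ids[0], ids[-1]
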