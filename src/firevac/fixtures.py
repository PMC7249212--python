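"""Seeded synthetic landscapes, road graphs and farm registries.

Every generator draws from its own pseudo-random stream derived from the
master seed by labeled sub-seeding, so adding a generator never perturbs
existing fixtures and a fixed seed yields byte-identical outputs.

The default grid is 100 x 100 cells at 20 m resolution on a UTM-like
synthetic origin — small enough for second-scale tests while matching the
resolution the simulator expects.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
import numpy as np

from firevac.fire import FirePerimeter, RosParameters, simulate
from firevac.raster import (
    PointSet,
    Raster,
    WindField,
    write_points,
    write_raster,
)
from firevac.roads import RoadEdge, RoadGraph, write_road_graph
from firevac.routing import AvailabilityFunction, EvacuationPlan, find_opera

__all__ = [
    "FixtureSpec",
    "DemoScenario",
    "make_landscape",
    "make_road_graph",
    "make_farms",
    "make_case_demo",
    "write_fixture_dir",
]

DEM_STYLES = ("flat", "ramp", "gaussian_hill")
FUEL_STYLES = ("uniform", "mosaic")
ROAD_STYLES = ("chain", "diamond", "grid")

# labeled sub-seeding: one fixed stream label per generator
_STREAM = {"dem": 11, "fuel": 12, "wind": 13, "roads": 21, "farms": 31, "demo": 41}

DEFAULT_ORIGIN = (500_000.0, 4_500_000.0)  # synthetic UTM-like metres
DEFAULT_CRS_TAG = "synthetic metric UTM-like"


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAM[stream]])


@dataclass
class FixtureSpec:
    """Declarative description of one synthetic scenario."""

    seed: int = 0
    shape: tuple[int, int] = (100, 100)
    cell_size: float = 20.0
    origin: tuple[float, float] = DEFAULT_ORIGIN
    dem_style: str = "flat"
    base_elevation: float = 100.0
    ramp_gradient: float = 0.1          # rise/run for the "ramp" style
    hill_height: float = 300.0          # peak height for "gaussian_hill"
    fuel_style: str = "uniform"
    uniform_fuel_class: int = 9
    humidity: float = 0.3
    wind_speed: float = 0.0             # m/h
    wind_direction: float = 0.0         # degrees FROM
    n_wind_steps: int = 1
    road_style: str = "grid"
    chain_length: int = 5
    grid_k: int = 4
    jitter: float = 30.0                # m of node-coordinate perturbation
    v_free: float = 30_000.0            # m/h free-flow speed
    farm_count: int = 10

    def __post_init__(self) -> None:
        if self.dem_style not in DEM_STYLES:
            raise ValueError(f"invalid dem style {self.dem_style!r}; expected {DEM_STYLES}")
        if self.fuel_style not in FUEL_STYLES:
            raise ValueError(f"invalid fuel style {self.fuel_style!r}; expected {FUEL_STYLES}")
        if self.road_style not in ROAD_STYLES:
            raise ValueError(f"invalid road style {self.road_style!r}; expected {ROAD_STYLES}")

    @property
    def extent(self) -> tuple[float, float, float, float]:
        x0, y0 = self.origin
        nrows, ncols = self.shape
        return (x0, y0 - nrows * self.cell_size, x0 + ncols * self.cell_size, y0)


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------

def make_landscape(spec: FixtureSpec) -> tuple[Raster, Raster, Raster, list[WindField]]:
    """Generate aligned DEM, fuel and humidity rasters plus a wind sequence."""
    nrows, ncols = spec.shape
    mk = lambda vals: Raster(values=vals, origin=spec.origin, cell_size=spec.cell_size,
                             crs_tag=DEFAULT_CRS_TAG)

    if spec.dem_style == "flat":
        dem_vals = np.full(spec.shape, spec.base_elevation)
    elif spec.dem_style == "ramp":
        # elevation rises northward at the configured gradient
        rows = np.arange(nrows)[:, None]
        dem_vals = spec.base_elevation + spec.ramp_gradient * spec.cell_size * (nrows - 1 - rows)
        dem_vals = np.broadcast_to(dem_vals, spec.shape).copy()
    else:  # gaussian_hill
        r = np.arange(nrows)[:, None] - (nrows - 1) / 2
        c = np.arange(ncols)[None, :] - (ncols - 1) / 2
        sigma = min(nrows, ncols) / 6.0
        dem_vals = spec.base_elevation + spec.hill_height * np.exp(
            -(r**2 + c**2) / (2 * sigma**2)
        )
    dem = mk(dem_vals.astype(float))

    if spec.fuel_style == "uniform":
        fuel_vals = np.full(spec.shape, float(spec.uniform_fuel_class))
    else:  # mosaic: blocky categorical patches over all 13 classes
        rng = _rng(spec.seed, "fuel")
        block = 10
        br, bc = math.ceil(nrows / block), math.ceil(ncols / block)
        patches = rng.integers(1, 14, size=(br, bc))
        fuel_vals = np.kron(patches, np.ones((block, block)))[:nrows, :ncols].astype(float)
    fuel = mk(fuel_vals)

    if not 0.0 <= spec.humidity <= 1.0:
        raise ValueError("humidity must be in [0, 1]")
    humidity = mk(np.full(spec.shape, float(spec.humidity)))

    winds = [WindField(speed=spec.wind_speed, direction_deg=spec.wind_direction)
             for _ in range(max(1, spec.n_wind_steps))]
    return dem, fuel, humidity, winds


# ---------------------------------------------------------------------------
# Road graphs
# ---------------------------------------------------------------------------

def _two_way(graph: RoadGraph, u: str, v: str, phi_uv: float, phi_vu: float,
             v_free: float) -> None:
    (x1, y1), (x2, y2) = graph.nodes[u], graph.nodes[v]
    length = math.hypot(x2 - x1, y2 - y1)
    graph.add_edge(RoadEdge(u, v, length=length, phi=phi_uv, v_free=v_free))
    graph.add_edge(RoadEdge(v, u, length=length, phi=phi_vu, v_free=v_free))


def make_road_graph(spec: FixtureSpec) -> RoadGraph:
    """Generate a connected oriented road graph inside the raster extent.

    Styles: ``chain`` (n nodes in a line, forward + reverse edges),
    ``diamond`` (the canonical 4-node two-route oracle fixture) and ``grid``
    (k x k junctions with jittered coordinates and random traffic weights).
    """
    rng = _rng(spec.seed, "roads")
    xmin, ymin, xmax, ymax = spec.extent
    pad = 0.1 * (xmax - xmin)

    if spec.road_style == "chain":
        n = spec.chain_length
        if n < 2:
            raise ValueError("chain needs >= 2 nodes")
        xs = np.linspace(xmin + pad, xmax - pad, n)
        y = (ymin + ymax) / 2
        graph = RoadGraph(nodes={f"n{i}": (float(xs[i]), float(y)) for i in range(n)})
        phis = rng.uniform(0.0, 0.8, size=(n - 1, 2))
        for i in range(n - 1):
            _two_way(graph, f"n{i}", f"n{i+1}", float(phis[i, 0]), float(phis[i, 1]),
                     spec.v_free)
        return graph

    if spec.road_style == "diamond":
        cx, cy = (xmin + xmax) / 2, (ymin + ymax) / 2
        half = (xmax - xmin) / 2 - pad
        graph = RoadGraph(
            nodes={
                "src": (cx - half, cy),
                "mid_short": (cx, cy + half / 2),
                "mid_long": (cx, cy - half),
                "dst": (cx + half, cy),
            }
        )
        phis = rng.uniform(0.0, 0.5, size=4)
        graph.add_edge(RoadEdge("src", "mid_short", length=half, phi=float(phis[0]),
                                v_free=spec.v_free))
        graph.add_edge(RoadEdge("mid_short", "dst", length=half, phi=float(phis[1]),
                                v_free=spec.v_free))
        long_leg = math.hypot(half, half)
        graph.add_edge(RoadEdge("src", "mid_long", length=long_leg, phi=float(phis[2]),
                                v_free=spec.v_free))
        graph.add_edge(RoadEdge("mid_long", "dst", length=long_leg, phi=float(phis[3]),
                                v_free=spec.v_free))
        return graph

    # grid
    k = spec.grid_k
    if k < 2:
        raise ValueError("grid needs k >= 2")
    xs = np.linspace(xmin + pad, xmax - pad, k)
    ys = np.linspace(ymin + pad, ymax - pad, k)
    jit = rng.uniform(-spec.jitter, spec.jitter, size=(k, k, 2))
    nodes = {
        f"g{i}_{j}": (float(xs[j] + jit[i, j, 0]), float(ys[i] + jit[i, j, 1]))
        for i in range(k)
        for j in range(k)
    }
    graph = RoadGraph(nodes=nodes)
    for i in range(k):
        for j in range(k):
            if j + 1 < k:
                p = rng.uniform(0.0, 0.8, size=2)
                _two_way(graph, f"g{i}_{j}", f"g{i}_{j+1}", float(p[0]), float(p[1]),
                         spec.v_free)
            if i + 1 < k:
                p = rng.uniform(0.0, 0.8, size=2)
                _two_way(graph, f"g{i}_{j}", f"g{i+1}_{j}", float(p[0]), float(p[1]),
                         spec.v_free)
    return graph


def make_farms(spec: FixtureSpec) -> PointSet:
    """Farm points scattered uniformly over the raster extent."""
    rng = _rng(spec.seed, "farms")
    xmin, ymin, xmax, ymax = spec.extent
    pts = [
        (f"farm{i}", float(rng.uniform(xmin, xmax)), float(rng.uniform(ymin, ymax)))
        for i in range(spec.farm_count)
    ]
    return PointSet(points=pts, kind_tag="farm")


# ---------------------------------------------------------------------------
# End-to-end demo scenario
# ---------------------------------------------------------------------------

@dataclass
class DemoScenario:
    """A bundled scenario exercising the full simulate -> route pipeline."""

    spec: FixtureSpec
    dem: Raster
    fuel: Raster
    humidity: Raster
    winds: list[WindField]
    params: RosParameters
    graph: RoadGraph
    farms: PointSet
    ignitions: PointSet
    source: str
    sink: str
    depart: float
    dt: float
    horizon: float
    snapshot_every: float
    snapshots: list[FirePerimeter]
    arrival: Raster
    avail: AvailabilityFunction
    plan: EvacuationPlan
    nofire_plan: EvacuationPlan


def make_case_demo(seed: int = 0) -> DemoScenario:
    """Build the packaged end-to-end scenario.

    A grid road network sits on a flat landscape; the ignition is placed on
    the second junction of the no-fire optimal route, so the router must
    reject at least that junction and detour — while still finding a
    feasible plan to the far-corner sink.
    """
    spec = FixtureSpec(
        seed=seed,
        dem_style="flat",
        fuel_style="uniform",
        uniform_fuel_class=9,
        humidity=0.3,
        road_style="grid",
        grid_k=4,
    )
    dem, fuel, humidity, _ = make_landscape(spec)
    graph = make_road_graph(spec)
    farms = make_farms(spec)
    params = RosParameters()
    source, sink = "g0_0", f"g{spec.grid_k-1}_{spec.grid_k-1}"
    depart, dt, horizon, snapshot_every = 0.0, 1.0, 60.0, 5.0

    no_fire = AvailabilityFunction(arrival=None, horizon=horizon)
    nofire_plan = find_opera(graph, no_fire, source, sink, depart)
    if not nofire_plan.feasible or len(nofire_plan.nodes) < 3:
        raise RuntimeError("demo grid must admit a multi-hop no-fire route")
    burn_node = nofire_plan.nodes[1]
    bx, by = graph.nodes[burn_node]
    ignitions = PointSet(points=[("ignition", bx, by)], kind_tag="ignition")

    snapshots, arrival = simulate(
        ignitions, dem, fuel, humidity, WindField(0.0, 0.0), params,
        dt=dt, horizon=horizon, snapshot_every=snapshot_every,
    )
    avail = AvailabilityFunction(arrival=arrival, safety_margin=0.0, horizon=horizon)
    plan = find_opera(graph, avail, source, sink, depart)
    return DemoScenario(
        spec=spec, dem=dem, fuel=fuel, humidity=humidity,
        winds=[WindField(0.0, 0.0)], params=params, graph=graph, farms=farms,
        ignitions=ignitions, source=source, sink=sink, depart=depart,
        dt=dt, horizon=horizon, snapshot_every=snapshot_every,
        snapshots=snapshots, arrival=arrival, avail=avail,
        plan=plan, nofire_plan=nofire_plan,
    )


# ---------------------------------------------------------------------------
# Fixture directory writer (gen-fixtures CLI backend)
# ---------------------------------------------------------------------------

def write_fixture_dir(spec: FixtureSpec, out_dir: str | Path) -> dict:
    """Write all fixture layers for a spec into a directory, plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dem, fuel, humidity, winds = make_landscape(spec)
    graph = make_road_graph(spec)
    farms = make_farms(spec)
    write_raster(dem, out / "dem.asc")
    write_raster(fuel, out / "fuel.asc")
    write_raster(humidity, out / "humidity.asc")
    write_road_graph(graph, out / "roads.geojson", nodes_csv=out / "nodes.csv")
    write_points(farms, out / "farms.csv")
    xmin, ymin, xmax, ymax = spec.extent
    ignition = PointSet(
        points=[("ignition", (xmin + xmax) / 2, (ymin + ymax) / 2)], kind_tag="ignition"
    )
    write_points(ignition, out / "ignition.csv")
    wind_doc = [{"speed_m_per_h": w.speed, "direction_deg_from": w.direction_deg}
                for w in winds]
    (out / "wind.json").write_text(json.dumps(wind_doc, indent=2) + "\n")
    manifest = {
        "seed": spec.seed,
        "shape": list(spec.shape),
        "cell_size": spec.cell_size,
        "origin": list(spec.origin),
        "dem_style": spec.dem_style,
        "fuel_style": spec.fuel_style,
        "road_style": spec.road_style,
        "files": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
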