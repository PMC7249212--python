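"""Discrete-time fire-perimeter spread simulation.

The fire front is a set of simple polygon rings whose vertices advance
outward along their normals at the locally effective rate of spread:

    effective ROS = max ROS(fuel, humidity) x wind factor x slope factor

with both factors confined to [0, 1] so the effective rate never exceeds
the fuel-determined ceiling.  After each step the rings are repaired
(self-intersections removed, colliding rings merged by union) and densified
so no front segment exceeds one cell size — the standard housekeeping of a
Huygens-style front propagation.

The wind and slope limiting factors are configurable strategy functions;
the shipped defaults are documented closed forms chosen for smoothness and
the [0, 1] bound (see :func:`wind_effect` and :func:`slope_effect`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import MultiPolygon, Polygon
from shapely.ops import unary_union

from firevac.raster import PointSet, Raster, WindField, check_aligned

__all__ = [
    "RosParameters",
    "FirePerimeter",
    "ros_max",
    "wind_effect",
    "slope_effect",
    "effective_ros",
    "step_perimeter",
    "simulate",
    "ignition_seed",
    "densify_ring",
    "dem_gradient",
    "perimeters_to_geojson",
    "write_perimeters",
    "FireError",
]

class FireError(ValueError):
    """Raised on fire-simulation contract violations."""


# Order-of-magnitude default maximum rates of spread (m/h) for the 13
# standard wildland fuel classes.  These are configuration data, not
# physics: override via RosParameters / a YAML config for real studies.
DEFAULT_ROS_MAX = {
    1: 5000.0,   # short grass
    2: 2500.0,   # timber grass / understory
    3: 6000.0,   # tall grass
    4: 5000.0,   # chaparral
    5: 1500.0,   # brush
    6: 2000.0,   # dormant brush
    7: 1500.0,   # southern rough
    8: 300.0,    # closed timber litter
    9: 600.0,    # hardwood litter
    10: 700.0,   # timber litter + understory
    11: 500.0,   # light logging slash
    12: 900.0,   # medium logging slash
    13: 1200.0,  # heavy logging slash
}


@dataclass
class RosParameters:
    """Rate-of-spread configuration.

    ``ros_max_by_fuel`` maps each fuel class (1..13) to its maximum rate of
    spread in m/h.  ``humidity_damping`` scales an exponential reduction
    ``exp(-k * humidity)``.  ``wind_saturation_speed`` is the wind speed (m/h)
    at which the directional wind effect saturates.  ``slope_coefficient``
    controls how strongly downhill spread is damped.
    """

    ros_max_by_fuel: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_ROS_MAX))
    humidity_damping: float = 2.0
    wind_saturation_speed: float = 30000.0
    slope_coefficient: float = 1.0

    def __post_init__(self) -> None:
        for fuel, ros in self.ros_max_by_fuel.items():
            if ros < 0:
                raise FireError(f"ROS_max for fuel class {fuel} must be >= 0, got {ros}")
        if self.humidity_damping < 0:
            raise FireError("humidity_damping must be >= 0")
        if not self.wind_saturation_speed > 0:
            raise FireError("wind_saturation_speed must be > 0")
        if self.slope_coefficient < 0:
            raise FireError("slope_coefficient must be >= 0")

    @classmethod
    def from_dict(cls, data: dict) -> "RosParameters":
        table = {int(k): float(v) for k, v in (data.get("ros_max_by_fuel") or {}).items()}
        return cls(
            ros_max_by_fuel=table or dict(DEFAULT_ROS_MAX),
            humidity_damping=float(data.get("humidity_damping", 2.0)),
            wind_saturation_speed=float(data.get("wind_saturation_speed", 30000.0)),
            slope_coefficient=float(data.get("slope_coefficient", 1.0)),
        )


@dataclass
class FirePerimeter:
    """The burning front at one instant: closed simple rings + a timestamp.

    Each ring is an ``(n, 2)`` array of vertex coordinates in projected
    metres, counter-clockwise, without a repeated closing vertex.
    ``timestamp`` is minutes since ignition.
    """

    rings: list[np.ndarray]
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        if self.timestamp < 0:
            raise FireError("timestamp must be >= 0")
        clean = []
        for ring in self.rings:
            arr = np.asarray(ring, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
                raise FireError("each perimeter ring needs >= 3 vertices of (x, y)")
            clean.append(arr)
        self.rings = clean

    def to_multipolygon(self) -> MultiPolygon:
        polys = [Polygon(ring) for ring in self.rings]
        geom = unary_union([shapely.make_valid(p) for p in polys])
        if geom.geom_type == "Polygon":
            geom = MultiPolygon([geom])
        return geom

    @property
    def area(self) -> float:
        return self.to_multipolygon().area

    @classmethod
    def from_geometry(cls, geom, timestamp: float) -> "FirePerimeter":
        """Build from a (Multi)Polygon, keeping exterior rings only."""
        polys = _polygons_of(geom)
        rings = []
        for poly in polys:
            coords = np.asarray(poly.exterior.coords)[:-1]
            if not poly.exterior.is_ccw:
                coords = coords[::-1]
            rings.append(coords)
        return cls(rings=rings, timestamp=timestamp)


def _polygons_of(geom) -> list[Polygon]:
    if geom.is_empty:
        return []
    if geom.geom_type == "Polygon":
        return [geom]
    if geom.geom_type in ("MultiPolygon", "GeometryCollection"):
        out: list[Polygon] = []
        for g in geom.geoms:
            out.extend(_polygons_of(g))
        return out
    return []


# ---------------------------------------------------------------------------
# Rate-of-spread components
# ---------------------------------------------------------------------------

def ros_max(fuel_class: int, humidity: float, params: RosParameters) -> float:
    """Maximum rate of spread (m/h) for a fuel class at a given humidity.

    ``table[fuel] * exp(-humidity_damping * humidity)``; always >= 0.
    """
    fuel = int(fuel_class)
    if fuel not in params.ros_max_by_fuel:
        raise FireError(f"unknown fuel class {fuel}: not in ROS table")
    if not 0.0 <= humidity <= 1.0:
        raise FireError(f"humidity must be in [0, 1], got {humidity}")
    return params.ros_max_by_fuel[fuel] * math.exp(-params.humidity_damping * humidity)


def wind_effect(spread_direction: np.ndarray, wind: WindField, params: RosParameters) -> float:
    """Directional wind limiting factor in [0, 1].

    ``1 - (min(U, U_sat)/U_sat) * (1 - cos(theta)) / 2`` where ``theta`` is
    the angle between the spread direction (outward normal) and the downwind
    direction and ``U_sat`` the saturation speed.  Equals 1 under calm and
    directly downwind; smallest directly upwind.
    """
    if wind.speed == 0:
        return 1.0
    d = np.asarray(spread_direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0:
        return 1.0
    cos_theta = float(np.dot(d / norm, wind.downwind_vector()))
    cos_theta = max(-1.0, min(1.0, cos_theta))
    u = min(wind.speed, params.wind_saturation_speed) / params.wind_saturation_speed
    return 1.0 - u * (1.0 - cos_theta) / 2.0


def slope_effect(spread_direction: np.ndarray, local_gradient: np.ndarray,
                 params: RosParameters) -> float:
    """Slope limiting factor in [0, 1].

    The gradient is the dimensionless rise/run vector of the terrain.  Spread
    with an uphill component is unpenalized (factor 1); downhill spread is
    damped as ``1 - s*c/(1 + s*c)`` where ``s`` is the downhill steepness
    along the spread direction and ``c`` the slope coefficient.
    """
    if params.slope_coefficient == 0:
        return 1.0
    d = np.asarray(spread_direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0:
        return 1.0
    g_along = float(np.dot(d / norm, np.asarray(local_gradient, dtype=float)))
    downhill = max(0.0, -g_along)
    damp = params.slope_coefficient * downhill
    return 1.0 - damp / (1.0 + damp)


def effective_ros(ros_max_value: float, wind_factor: float, slope_factor: float) -> float:
    """Effective rate of spread: the product of ceiling and limiting factors."""
    if ros_max_value < 0:
        raise FireError(f"ros_max must be >= 0, got {ros_max_value}")
    for name, f in (("wind", wind_factor), ("slope", slope_factor)):
        if not 0.0 <= f <= 1.0:
            raise FireError(f"{name} factor outside [0, 1]: {f}")
    return ros_max_value * wind_factor * slope_factor


# ---------------------------------------------------------------------------
# DEM gradient
# ---------------------------------------------------------------------------

def dem_gradient(dem: Raster) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference gradient (dz/dx, dz/dy) of the DEM, rise/run.

    Row 0 is north, so dz/dy = -d(values)/d(row).
    """
    dz_drow, dz_dcol = np.gradient(dem.values, dem.cell_size)
    return dz_dcol, -dz_drow


def _sample_gradient(gx: np.ndarray, gy: np.ndarray, dem: Raster,
                     x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Gradient vectors at arbitrary points (nearest-cell lookup, clipped)."""
    x0, y0 = dem.origin
    col = np.clip(((x - x0) / dem.cell_size).astype(int), 0, dem.ncols - 1)
    row = np.clip(((y0 - y) / dem.cell_size).astype(int), 0, dem.nrows - 1)
    return np.stack([gx[row, col], gy[row, col]], axis=1)


def _sample_cells(raster: Raster, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    x0, y0 = raster.origin
    col = np.clip(((x - x0) / raster.cell_size).astype(int), 0, raster.ncols - 1)
    row = np.clip(((y0 - y) / raster.cell_size).astype(int), 0, raster.nrows - 1)
    return raster.values[row, col]


# ---------------------------------------------------------------------------
# Ring geometry helpers
# ---------------------------------------------------------------------------

def _ensure_ccw(ring: np.ndarray) -> np.ndarray:
    # shoelace signed area; CCW = positive
    x, y = ring[:, 0], ring[:, 1]
    area2 = np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))
    return ring if area2 > 0 else ring[::-1]


def outward_normals(ring: np.ndarray) -> np.ndarray:
    """Per-vertex outward unit normals of a CCW ring (bisector of neighbours)."""
    ring = _ensure_ccw(np.asarray(ring, dtype=float))
    prev = np.roll(ring, 1, axis=0)
    nxt = np.roll(ring, -1, axis=0)
    e_in = ring - prev
    e_out = nxt - ring

    def seg_normal(e: np.ndarray) -> np.ndarray:
        # right-hand normal of a CCW edge points outward
        n = np.stack([e[:, 1], -e[:, 0]], axis=1)
        lens = np.linalg.norm(n, axis=1, keepdims=True)
        lens[lens == 0] = 1.0
        return n / lens

    n = seg_normal(e_in) + seg_normal(e_out)
    lens = np.linalg.norm(n, axis=1, keepdims=True)
    # degenerate (reflex 180deg) vertices: fall back to incoming-segment normal
    bad = (lens[:, 0] < 1e-12)
    if bad.any():
        n[bad] = seg_normal(e_in)[bad]
        lens = np.linalg.norm(n, axis=1, keepdims=True)
        lens[lens == 0] = 1.0
    return n / lens


def densify_ring(ring: np.ndarray, spacing: float) -> np.ndarray:
    """Subdivide ring segments longer than ``spacing``, keeping every
    original vertex (the polygon's geometry is unchanged, so footprint
    containment across steps stays exact)."""
    ring = np.asarray(ring, dtype=float)
    out: list[np.ndarray] = []
    n = len(ring)
    for i in range(n):
        a, b = ring[i], ring[(i + 1) % n]
        out.append(a)
        seg_len = float(np.linalg.norm(b - a))
        if seg_len > spacing:
            k = int(math.ceil(seg_len / spacing))
            for j in range(1, k):
                out.append(a + (b - a) * (j / k))
    arr = np.array(out)
    # drop consecutive duplicates (exact, no area change)
    keep = np.any(arr != np.roll(arr, 1, axis=0), axis=1)
    keep[0] = True
    return arr[keep]


def ignition_seed(x: float, y: float, radius: float, n_vertices: int = 16) -> np.ndarray:
    """Regular polygon seed ring around an ignition point (a point has no normals)."""
    angles = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    return np.stack([x + radius * np.cos(angles), y + radius * np.sin(angles)], axis=1)


# ---------------------------------------------------------------------------
# Perimeter stepping
# ---------------------------------------------------------------------------

def _vertex_ros(ring: np.ndarray, normals: np.ndarray, fuel: Raster, humidity: Raster,
                gx: np.ndarray, gy: np.ndarray, dem: Raster, wind: WindField,
                params: RosParameters) -> np.ndarray:
    x, y = ring[:, 0], ring[:, 1]
    fuel_vals = _sample_cells(fuel, x, y)
    hum_vals = np.clip(_sample_cells(humidity, x, y), 0.0, 1.0)
    grads = _sample_gradient(gx, gy, dem, x, y)
    out = np.empty(len(ring))
    for i in range(len(ring)):
        f = int(fuel_vals[i])
        if f == int(fuel.nodata) or f not in params.ros_max_by_fuel:
            out[i] = 0.0
            continue
        rmax = ros_max(f, float(hum_vals[i]), params)
        w = wind_effect(normals[i], wind, params)
        s = slope_effect(normals[i], grads[i], params)
        out[i] = effective_ros(rmax, w, s)
    return out


def step_perimeter(state: FirePerimeter, dem: Raster, fuel: Raster, humidity: Raster,
                   wind: WindField, params: RosParameters, dt: float) -> FirePerimeter:
    """Advance the perimeter by one time step of ``dt`` minutes.

    Every vertex moves along its outward normal by ``effective ROS * dt/60``;
    the displaced rings are repaired to simple polygons, unioned with the
    previous footprint (fire never retreats), clipped to the raster extent
    and resampled.
    """
    if not dt > 0:
        raise FireError(f"dt must be > 0, got {dt}")
    check_aligned(dem, fuel, humidity)
    gx, gy = dem_gradient(dem)
    old_geom = state.to_multipolygon()
    new_polys = []
    for ring in state.rings:
        ring = _ensure_ccw(ring)
        normals = outward_normals(ring)
        ros = _vertex_ros(ring, normals, fuel, humidity, gx, gy, dem, wind, params)
        displaced = ring + normals * (ros[:, None] * dt / 60.0)
        poly = shapely.make_valid(Polygon(displaced))
        new_polys.append(poly)
    merged = unary_union(new_polys + [old_geom])
    xmin, ymin, xmax, ymax = dem.bounds
    merged = merged.intersection(shapely.box(xmin, ymin, xmax, ymax))
    polys = _polygons_of(merged)
    if not polys:
        raise FireError("perimeter degenerated to empty geometry")
    rings = []
    for poly in polys:
        coords = np.asarray(poly.exterior.coords)[:-1]
        if not poly.exterior.is_ccw:
            coords = coords[::-1]
        rings.append(densify_ring(coords, spacing=dem.cell_size))
    return FirePerimeter(rings=rings, timestamp=state.timestamp + dt)


# ---------------------------------------------------------------------------
# Full simulation
# ---------------------------------------------------------------------------

def simulate(
    ignitions: PointSet,
    dem: Raster,
    fuel: Raster,
    humidity: Raster,
    wind_sequence: Sequence[WindField] | WindField,
    params: RosParameters,
    dt: float = 1.0,
    horizon: float = 60.0,
    snapshot_every: float | None = None,
) -> tuple[list[FirePerimeter], Raster]:
    """Run the discrete-time perimeter spread from the ignition points.

    Returns perimeter snapshots at the requested cadence (always including
    the initial seed at t = 0) and the arrival-time field: per cell, the
    first simulated minute at which the cell centre lay inside the fire
    footprint (nodata where never burned, time resolution = ``dt``).

    ``wind_sequence`` may be a single WindField (held constant) or one
    WindField per step.
    """
    if snapshot_every is None:
        snapshot_every = dt
    if not dt > 0:
        raise FireError("dt must be > 0")
    if horizon < 0:
        raise FireError("horizon must be >= 0")
    n_steps = int(round(horizon / dt))
    if abs(n_steps * dt - horizon) > 1e-9 * max(1.0, horizon):
        raise FireError("horizon must be a multiple of dt")
    snap_stride = int(round(snapshot_every / dt))
    if abs(snap_stride * dt - snapshot_every) > 1e-9 or snap_stride < 1:
        raise FireError("snapshot_every must be a positive multiple of dt")
    check_aligned(dem, fuel, humidity)
    if len(ignitions) == 0:
        raise FireError("no ignition points given")
    for pid, x, y in ignitions:
        if not dem.contains_point(x, y):
            raise FireError(f"ignition {pid!r} at ({x}, {y}) outside raster extent")

    if isinstance(wind_sequence, WindField):
        winds = [wind_sequence] * max(n_steps, 1)
    else:
        winds = list(wind_sequence)
        if len(winds) < n_steps:
            winds = winds + [winds[-1]] * (n_steps - len(winds))

    seed_rings = [ignition_seed(x, y, radius=dem.cell_size) for _, x, y in ignitions]
    state = FirePerimeter(rings=seed_rings, timestamp=0.0)

    arrival = dem.copy_with(np.full(dem.shape, dem.nodata))
    arrival.nodata = dem.nodata
    X, Y = dem.cell_centers()
    unburned = np.ones(dem.shape, dtype=bool)
    _update_arrival(arrival, state, X, Y, unburned, t=0.0)

    snapshots = [state]
    for step in range(n_steps):
        state = step_perimeter(state, dem, fuel, humidity, winds[step], params, dt)
        _update_arrival(arrival, state, X, Y, unburned, t=state.timestamp)
        if (step + 1) % snap_stride == 0:
            snapshots.append(state)
    return snapshots, arrival


def _update_arrival(arrival: Raster, state: FirePerimeter, X: np.ndarray, Y: np.ndarray,
                    unburned: np.ndarray, t: float) -> None:
    geom = state.to_multipolygon()
    if geom.is_empty:
        return
    xmin, ymin, xmax, ymax = geom.bounds
    cand = unburned & (X >= xmin) & (X <= xmax) & (Y >= ymin) & (Y <= ymax)
    idx = np.nonzero(cand)
    if idx[0].size == 0:
        return
    inside = shapely.contains_xy(geom, X[idx], Y[idx])
    rows, cols = idx[0][inside], idx[1][inside]
    arrival.values[rows, cols] = t
    unburned[rows, cols] = False


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def perimeters_to_geojson(snapshots: Sequence[FirePerimeter]) -> dict:
    """One MultiPolygon feature per snapshot, tagged with its minute."""
    features = []
    for snap in snapshots:
        geom = snap.to_multipolygon()
        features.append(
            {
                "type": "Feature",
                "geometry": json.loads(shapely.to_geojson(geom)),
                "properties": {"t_min": snap.timestamp},
            }
        )
    return {"type": "FeatureCollection", "features": features}


def write_perimeters(snapshots: Sequence[FirePerimeter], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(perimeters_to_geojson(snapshots), sort_keys=True) + "\n")
    return path
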