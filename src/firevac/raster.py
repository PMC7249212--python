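"""Raster and vector layer I/O with geospatial contract enforcement.

Rasters are georeferenced 2-D fields (elevation in metres, integer fuel
class, or humidity fraction) on a shared metric projected grid.  The only
on-disk raster format is the ESRI ASCII grid (``.asc``), a plain-text
format that round-trips byte-identically.  Point sets are read from CSV
(``id,x,y``) or GeoJSON Point feature collections.

Grid convention: cell ``(row, col)`` maps to its cell-centre coordinates;
row 0 is the northernmost row.  The package never reprojects — it only
validates that units are metres and that all layers entering the simulator
agree on shape, origin and cell size.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np

__all__ = [
    "Raster",
    "WindField",
    "PointSet",
    "read_raster",
    "write_raster",
    "read_points",
    "write_points",
    "check_aligned",
    "RasterError",
    "PointSetError",
]

DEFAULT_NODATA = -9999.0

LAYER_KINDS = ("dem", "fuel", "humidity")

#: Degree-unit CRS markers rejected by :func:`read_raster` / Raster validation.
_GEOGRAPHIC_MARKERS = ("degree", "epsg:4326", "wgs84 (geographic)", "longlat", "geogcs")


class RasterError(ValueError):
    """Raised on raster contract violations (format, CRS, value range)."""


class PointSetError(ValueError):
    """Raised on point-set contract violations."""


@dataclass
class Raster:
    """A georeferenced 2-D grid of values on a metric projected CRS.

    Parameters
    ----------
    values:
        2-D float array, row 0 = northernmost row.
    origin:
        ``(x, y)`` of the grid's **top-left corner** in projected metres.
    cell_size:
        Metres per (square) cell, > 0.
    nodata:
        Sentinel marking missing cells.
    crs_tag:
        Free-text label of the projected CRS; must not indicate degree units.
    """

    values: np.ndarray
    origin: tuple[float, float]
    cell_size: float
    nodata: float = DEFAULT_NODATA
    crs_tag: str = "metric"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise RasterError("raster values must be a non-empty 2-D array")
        if not self.cell_size > 0:
            raise RasterError(f"cell_size must be > 0, got {self.cell_size}")
        tag = self.crs_tag.lower()
        if any(marker in tag for marker in _GEOGRAPHIC_MARKERS):
            raise RasterError(
                f"geographic (degree-unit) CRS rejected: {self.crs_tag!r}; "
                "a metric projected CRS (e.g. UTM) is required"
            )

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid extent in metres."""
        x0, y0 = self.origin
        return (x0, y0 - self.nrows * self.cell_size, x0 + self.ncols * self.cell_size, y0)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        return (x0 + (col + 0.5) * self.cell_size, y0 - (row + 0.5) * self.cell_size)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized cell-centre coordinates as ``(X, Y)`` 2-D arrays."""
        x0, y0 = self.origin
        cols = x0 + (np.arange(self.ncols) + 0.5) * self.cell_size
        rows = y0 - (np.arange(self.nrows) + 0.5) * self.cell_size
        return np.meshgrid(cols, rows)

    def index_of(self, x: float, y: float) -> tuple[int, int] | None:
        """Return ``(row, col)`` containing the point, or ``None`` if outside."""
        x0, y0 = self.origin
        col = int(math.floor((x - x0) / self.cell_size))
        row = int(math.floor((y0 - y) / self.cell_size))
        if 0 <= row < self.nrows and 0 <= col < self.ncols:
            return (row, col)
        return None

    def contains_point(self, x: float, y: float) -> bool:
        return self.index_of(x, y) is not None

    def mask_valid(self) -> np.ndarray:
        return self.values != self.nodata

    def copy_with(self, values: np.ndarray) -> "Raster":
        return Raster(
            values=np.array(values, dtype=float),
            origin=self.origin,
            cell_size=self.cell_size,
            nodata=self.nodata,
            crs_tag=self.crs_tag,
        )


@dataclass(frozen=True)
class WindField:
    """Spatially uniform wind: average speed and the direction it blows FROM.

    ``direction_deg`` uses the meteorological convention (degrees clockwise
    from north, direction of origin) and is normalized to ``[0, 360)``.
    Speed is in m/h.
    """

    speed: float
    direction_deg: float

    def __post_init__(self) -> None:
        if self.speed < 0:
            raise ValueError(f"wind speed must be >= 0, got {self.speed}")
        object.__setattr__(self, "direction_deg", self.direction_deg % 360.0)

    def downwind_vector(self) -> np.ndarray:
        """Unit vector (east, north components) of the direction wind blows TO."""
        theta = math.radians(self.direction_deg)
        return np.array([-math.sin(theta), -math.cos(theta)])


@dataclass
class PointSet:
    """A collection of identified points (farms, ignitions) in projected metres."""

    points: list[tuple[str, float, float]]
    kind_tag: str = "point"

    def __post_init__(self) -> None:
        ids = [p[0] for p in self.points]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise PointSetError(f"duplicate point ids: {dupes}")
        for pid, x, y in self.points:
            if not (math.isfinite(x) and math.isfinite(y)):
                raise PointSetError(f"non-finite coordinate for point {pid!r}: ({x}, {y})")

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self) -> Iterator[tuple[str, float, float]]:
        return iter(self.points)

    def coords(self) -> np.ndarray:
        return np.array([(x, y) for _, x, y in self.points], dtype=float).reshape(-1, 2)


# ---------------------------------------------------------------------------
# Layer-kind validation
# ---------------------------------------------------------------------------

FUEL_CLASSES = tuple(range(1, 14))  # the 13 standard wildland fuel classes


def _validate_layer(raster: Raster, layer_kind: str) -> None:
    if layer_kind not in LAYER_KINDS:
        raise RasterError(f"unknown layer kind {layer_kind!r}; expected one of {LAYER_KINDS}")
    valid = raster.mask_valid()
    vals = raster.values[valid]
    if layer_kind == "fuel":
        if vals.size and not np.all(np.equal(np.mod(vals, 1), 0)):
            raise RasterError("fuel classes must be integers")
        if vals.size and (vals.min() < 1 or vals.max() > 13):
            bad = sorted(set(vals[(vals < 1) | (vals > 13)].astype(int).tolist()))
            raise RasterError(f"fuel class out of range 1..13: {bad}")
    elif layer_kind == "humidity":
        if vals.size and (vals.min() < 0 or vals.max() > 1):
            raise RasterError("humidity values must lie in [0, 1]")


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

def read_raster(path: str | Path, layer_kind: str = "dem", crs_tag: str = "metric") -> Raster:
    """Read an ESRI ASCII grid and validate it for the given layer kind.

    A sidecar ``.prj`` file, if present, is inspected: grids whose CRS is
    geographic (degree units) are rejected, since all downstream geometry
    assumes metres.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster file not found: {path}")
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if not data_lines and key in (
                "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter", "yllcenter",
                "cellsize", "nodata_value",
            ):
                header[key] = float(parts[1])
            else:
                data_lines.append(line)
    for required in ("ncols", "nrows", "cellsize"):
        if required not in header:
            raise RasterError(f"malformed ASCII grid {path}: missing header key {required!r}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    cell_size = header["cellsize"]
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    if "xllcorner" in header:
        xll, yll = header["xllcorner"], header["yllcorner"]
    else:  # cell-centre registration
        xll = header["xllcenter"] - cell_size / 2
        yll = header["yllcenter"] - cell_size / 2
    values = np.loadtxt(data_lines, dtype=float, ndmin=2)
    if values.shape != (nrows, ncols):
        raise RasterError(
            f"ASCII grid {path}: data shape {values.shape} does not match "
            f"header ({nrows}, {ncols})"
        )
    prj = path.with_suffix(".prj")
    if prj.exists():
        wkt = prj.read_text().lower()
        if "degree" in wkt or ("geogcs" in wkt and "projcs" not in wkt):
            raise RasterError(f"geographic (degree-unit) CRS rejected for {path}")
        crs_tag = prj.read_text().strip() or crs_tag
    origin = (xll, yll + nrows * cell_size)
    raster = Raster(values=values, origin=origin, cell_size=cell_size,
                    nodata=nodata, crs_tag=crs_tag)
    _validate_layer(raster, layer_kind)
    return raster


def _format_value(v: float) -> str:
    if float(v).is_integer():
        return str(int(v))
    return repr(float(v))


def write_raster(raster: Raster, path: str | Path) -> Path:
    """Write a raster as a canonical ESRI ASCII grid (byte-stable round trip)."""
    path = Path(path)
    x0, y0 = raster.origin
    yll = y0 - raster.nrows * raster.cell_size
    lines = [
        f"ncols {raster.ncols}",
        f"nrows {raster.nrows}",
        f"xllcorner {_format_value(x0)}",
        f"yllcorner {_format_value(yll)}",
        f"cellsize {_format_value(raster.cell_size)}",
        f"NODATA_value {_format_value(raster.nodata)}",
    ]
    for row in raster.values:
        lines.append(" ".join(_format_value(v) for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path


def check_aligned(*rasters: Raster) -> None:
    """Require that all rasters share grid shape, origin and cell size."""
    if not rasters:
        return
    ref = rasters[0]
    for other in rasters[1:]:
        if (
            other.shape != ref.shape
            or other.origin != ref.origin
            or other.cell_size != ref.cell_size
        ):
            raise RasterError(
                "misaligned rasters: "
                f"{ref.shape}@{ref.origin}/{ref.cell_size} vs "
                f"{other.shape}@{other.origin}/{other.cell_size}"
            )


# ---------------------------------------------------------------------------
# Point sets (CSV / GeoJSON)
# ---------------------------------------------------------------------------

def read_points(path: str | Path, kind_tag: str = "point") -> PointSet:
    """Read a point set from CSV (columns ``id,x,y``) or GeoJSON Points."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"point file not found: {path}")
    if path.suffix.lower() in (".json", ".geojson"):
        return _read_points_geojson(path, kind_tag)
    return _read_points_csv(path, kind_tag)


def _read_points_csv(path: Path, kind_tag: str) -> PointSet:
    points: list[tuple[str, float, float]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"id", "x", "y"} <= set(reader.fieldnames):
            raise PointSetError(f"{path}: CSV must have columns id,x,y")
        for lineno, row in enumerate(reader, start=2):
            try:
                x, y = float(row["x"]), float(row["y"])
            except (TypeError, ValueError) as exc:
                raise PointSetError(f"{path}:{lineno}: non-numeric coordinate") from exc
            points.append((row["id"], x, y))
    return PointSet(points=points, kind_tag=kind_tag)


def _read_points_geojson(path: Path, kind_tag: str) -> PointSet:
    doc = json.loads(path.read_text())
    feats = doc.get("features", [])
    points: list[tuple[str, float, float]] = []
    for i, feat in enumerate(feats):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Point":
            raise PointSetError(f"{path}: feature {i} is not a Point")
        x, y = geom["coordinates"][:2]
        pid = str((feat.get("properties") or {}).get("id", i))
        if not isinstance(x, (int, float)) or not isinstance(y, (int, float)):
            raise PointSetError(f"{path}: feature {i} has non-numeric coordinates")
        points.append((pid, float(x), float(y)))
    return PointSet(points=points, kind_tag=kind_tag)


def write_points(points: PointSet, path: str | Path) -> Path:
    """Write a point set as CSV or GeoJSON depending on extension."""
    path = Path(path)
    if path.suffix.lower() in (".json", ".geojson"):
        doc = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [x, y]},
                    "properties": {"id": pid, "kind": points.kind_tag},
                }
                for pid, x, y in points
            ],
        }
        path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    else:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "x", "y"])
            for pid, x, y in points:
                writer.writerow([pid, repr(float(x)), repr(float(y))])
    return path
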