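"""Buffer-zone exposure classification of farm points around fire footprints.

Each farm is classified by its Euclidean distance to the nearest fire
footprint polygon (0 if inside): ``direct`` within the inner radius
(default 1 km), ``indirect`` between the inner and outer radius (default
7 km — the maximum flight range of a bee swarm), ``outside`` beyond.
Distances exactly equal to a radius fall in the inner class (<=).
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import shapely
from shapely.geometry import Point
from shapely.ops import unary_union

from firevac.raster import PointSet

__all__ = [
    "FarmExposure",
    "ExposureReport",
    "classify_farms",
    "footprints_from_geojson",
    "read_footprints",
    "write_report",
]

R_DIRECT_DEFAULT = 1000.0
R_INDIRECT_DEFAULT = 7000.0

CLASSES = ("direct", "indirect", "outside")


@dataclass(frozen=True)
class FarmExposure:
    """One farm's distance to the nearest fire footprint and its class."""

    farm_id: str
    distance_m: float
    exposure_class: str


@dataclass
class ExposureReport:
    """Per-farm exposure records plus class totals (totals sum to farm count)."""

    records: list[FarmExposure]
    r_direct: float
    r_indirect: float

    @property
    def totals(self) -> dict[str, int]:
        out = {c: 0 for c in CLASSES}
        for rec in self.records:
            out[rec.exposure_class] += 1
        return out

    def __len__(self) -> int:
        return len(self.records)


def classify_farms(
    farms: PointSet,
    footprints: Sequence,
    r_direct: float = R_DIRECT_DEFAULT,
    r_indirect: float = R_INDIRECT_DEFAULT,
) -> ExposureReport:
    """Classify each farm by distance to the nearest fire footprint.

    ``footprints`` is a sequence of shapely (Multi)Polygons; an empty
    sequence classifies every farm as outside (distance inf) with a warning.
    """
    if not r_direct < r_indirect:
        raise ValueError(f"r_direct ({r_direct}) must be < r_indirect ({r_indirect})")
    geoms = [g for g in footprints if g is not None and not g.is_empty]
    if not geoms:
        warnings.warn("empty footprint set: all farms classified as outside", stacklevel=2)
        records = [FarmExposure(pid, math.inf, "outside") for pid, _, _ in farms]
        return ExposureReport(records=records, r_direct=r_direct, r_indirect=r_indirect)
    merged = unary_union(geoms)
    records = []
    for pid, x, y in farms:
        d = float(merged.distance(Point(x, y)))  # 0 if inside
        if d <= r_direct:
            cls = "direct"
        elif d <= r_indirect:
            cls = "indirect"
        else:
            cls = "outside"
        records.append(FarmExposure(pid, d, cls))
    return ExposureReport(records=records, r_direct=r_direct, r_indirect=r_indirect)


def footprints_from_geojson(doc: dict) -> list:
    """Extract (Multi)Polygon geometries from a GeoJSON FeatureCollection."""
    geoms = []
    features = doc.get("features", []) if doc.get("type") == "FeatureCollection" else [doc]
    for feat in features:
        geom = feat.get("geometry") if "geometry" in feat else feat
        if geom and geom.get("type") in ("Polygon", "MultiPolygon"):
            geoms.append(shapely.geometry.shape(geom))
    return geoms


def read_footprints(path: str | Path) -> list:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"footprint file not found: {path}")
    return footprints_from_geojson(json.loads(path.read_text()))


def write_report(report: ExposureReport, csv_path: str | Path,
                 totals_path: str | Path | None = None) -> Path:
    """Write per-farm records as CSV and class totals as JSON."""
    csv_path = Path(csv_path)
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "distance_m", "class"])
        for rec in report.records:
            d = "inf" if math.isinf(rec.distance_m) else repr(rec.distance_m)
            writer.writerow([rec.farm_id, d, rec.exposure_class])
    if totals_path is not None:
        doc = {
            "totals": report.totals,
            "n_farms": len(report),
            "r_direct_m": report.r_direct,
            "r_indirect_m": report.r_indirect,
        }
        Path(totals_path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return csv_path
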