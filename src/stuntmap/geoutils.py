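"""Small geodesy and vector-geometry helpers shared across the pipeline.

Coordinates are WGS84 lon/lat degrees throughout.  Great-circle distances
use the haversine formula on a spherical Earth (R = 6371.0088 km, the
IUGG mean radius); planar degree coordinates are used for the mesh/FEM
kernel, with :func:`degrees_to_km` providing the reporting conversion at
a stated latitude.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import MultiPoint, Polygon, box, shape
from shapely.geometry.base import BaseGeometry

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between lon/lat points (degrees).

    Accepts scalars or broadcastable arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def destination_point(lon, lat, bearing_rad, distance_km):
    """Point reached from (lon, lat) travelling `distance_km` along a
    great circle with initial bearing `bearing_rad` (radians, from north).
    Vectorised over all arguments."""
    lon = np.radians(np.asarray(lon, dtype=float))
    lat = np.radians(np.asarray(lat, dtype=float))
    delta = np.asarray(distance_km, dtype=float) / EARTH_RADIUS_KM
    theta = np.asarray(bearing_rad, dtype=float)
    lat2 = np.arcsin(np.sin(lat) * np.cos(delta) + np.cos(lat) * np.sin(delta) * np.cos(theta))
    lon2 = lon + np.arctan2(
        np.sin(theta) * np.sin(delta) * np.cos(lat),
        np.cos(delta) - np.sin(lat) * np.sin(lat2),
    )
    return np.degrees(lon2), np.degrees(lat2)


def degrees_to_km(deg: float, mean_lat_deg: float = 0.0) -> float:
    """Convert a degree-scale distance to km at a stated latitude.

    One degree of latitude is ~111.19 km; longitudinal degrees shrink by
    cos(latitude).  This helper uses the geometric mean of the two, which
    is the natural isotropic conversion for an isotropic field.
    """
    km_per_deg_lat = math.pi * EARTH_RADIUS_KM / 180.0
    km_per_deg_lon = km_per_deg_lat * math.cos(math.radians(mean_lat_deg))
    return deg * math.sqrt(km_per_deg_lat * km_per_deg_lon)


@dataclass
class AdminUnit:
    """One administrative polygon (level 1 = state-like, level 2 = LGA-like)."""

    unit_id: str
    level: int
    geometry: BaseGeometry
    parent_id: str | None = None
    name: str | None = None


@dataclass
class AdminMap:
    """Two-level planar partition of a study domain.

    level-1 units partition the domain bbox; each level-1 unit is itself
    partitioned by its level-2 children.
    """

    bbox: tuple[float, float, float, float]  # lon_min, lat_min, lon_max, lat_max
    admin1: list[AdminUnit] = field(default_factory=list)
    admin2: list[AdminUnit] = field(default_factory=list)

    @property
    def domain(self) -> Polygon:
        return box(*self.bbox)

    def units(self, level: int) -> list[AdminUnit]:
        if level == 1:
            return self.admin1
        if level == 2:
            return self.admin2
        raise ValueError(f"admin level must be 1 or 2, got {level}")

    def to_geojson(self, level: int) -> dict:
        feats = []
        for u in self.units(level):
            feats.append(
                {
                    "type": "Feature",
                    "properties": {
                        "unit_id": u.unit_id,
                        "level": u.level,
                        "parent_id": u.parent_id,
                        "name": u.name,
                    },
                    "geometry": shapely.geometry.mapping(u.geometry),
                }
            )
        return {"type": "FeatureCollection", "features": feats}

    def write_geojson(self, path, level: int) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_geojson(level), fh)

    @classmethod
    def from_geojson(cls, admin1_path, admin2_path) -> "AdminMap":
        def _load(path, level):
            with open(path) as fh:
                fc = json.load(fh)
            out = []
            for feat in fc["features"]:
                p = feat.get("properties", {})
                out.append(
                    AdminUnit(
                        unit_id=str(p.get("unit_id")),
                        level=level,
                        geometry=shape(feat["geometry"]),
                        parent_id=p.get("parent_id"),
                        name=p.get("name"),
                    )
                )
            return out

        a1 = _load(admin1_path, 1)
        a2 = _load(admin2_path, 2)
        bounds = shapely.unary_union([u.geometry for u in a1]).bounds
        return cls(bbox=tuple(bounds), admin1=a1, admin2=a2)


def voronoi_partition(seeds: np.ndarray, domain: BaseGeometry) -> list[Polygon]:
    """Partition `domain` into cells, one per seed point (Voronoi, clipped).

    Cells are returned in seed order.  Degenerate slivers are dropped by
    intersecting with the domain; every returned polygon is valid.
    """
    seeds = np.asarray(seeds, dtype=float)
    if len(seeds) == 1:
        return [Polygon(domain)]
    cells = shapely.voronoi_polygons(MultiPoint(seeds), extend_to=domain.buffer(1.0))
    out: list[Polygon | None] = [None] * len(seeds)
    pts = [shapely.Point(s) for s in seeds]
    for cell in cells.geoms:
        clipped = cell.intersection(domain)
        if clipped.is_empty:
            continue
        for i, pt in enumerate(pts):
            if out[i] is None and cell.covers(pt):
                out[i] = clipped
                break
    # Safety: any seed that lost its cell to clipping gets nothing; caller
    # should supply seeds inside the domain so this does not happen.
    return [c for c in out if c is not None]
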