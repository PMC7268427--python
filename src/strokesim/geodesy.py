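"""Great-circle geometry and planar convex hulls.

Flight legs in the transport model are flown along the great circle at a
constant cruise speed, so the only geodesy needed is the haversine distance
on a spherical Earth (IUGG mean radius 6371.0088 km).  Hospital catchment
polygons are convex hulls of mission locations; hulls are computed after an
equirectangular projection centred on the point set, which preserves hull
membership at the national scales this model targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from shapely.geometry import MultiPoint
from shapely.geometry.polygon import orient

from .exceptions import ConfigurationError, InputError

#: IUGG mean Earth radius, km.
EARTH_RADIUS_KM = 6371.0088


class GeoPoint(NamedTuple):
    """A WGS84 coordinate pair in decimal degrees (latitude, longitude)."""

    lat: float
    lon: float

    def validate(self) -> "GeoPoint":
        if not (-90.0 <= self.lat <= 90.0) or not (-180.0 <= self.lon <= 180.0):
            raise InputError(f"coordinate out of range: lat={self.lat}, lon={self.lon}")
        return self


def great_circle_km(a: GeoPoint, b: GeoPoint) -> float:
    """Haversine great-circle distance between two points, in km.

    Symmetric, non-negative, and zero iff the coordinates coincide.
    Antipodal-safe (the haversine argument is clipped to [0, 1]).
    """
    a = GeoPoint(*a).validate()
    b = GeoPoint(*b).validate()
    phi1, phi2 = math.radians(a.lat), math.radians(b.lat)
    dphi = phi2 - phi1
    dlam = math.radians(b.lon - a.lon)
    h = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    h = min(1.0, max(0.0, h))
    return 2.0 * EARTH_RADIUS_KM * math.asin(math.sqrt(h))


def great_circle_km_vec(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Vectorised haversine; arguments in degrees, broadcast as numpy arrays."""
    phi1 = np.radians(np.asarray(lat1, dtype=float))
    phi2 = np.radians(np.asarray(lat2, dtype=float))
    dphi = phi2 - phi1
    dlam = np.radians(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    h = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def flight_time_min(distance_km: float, speed_kmh: float) -> float:
    """Cruise time in minutes for a great-circle leg; excludes dispatch delays."""
    if speed_kmh <= 0:
        raise ConfigurationError(f"flight speed must be positive, got {speed_kmh}")
    if distance_km < 0:
        raise InputError(f"distance must be non-negative, got {distance_km}")
    return distance_km / speed_kmh * 60.0


@dataclass(frozen=True)
class Polygon2D:
    """A closed, counter-clockwise ring of GeoPoints, or a flagged degenerate set.

    ``degenerate`` is True when the source points do not span a proper polygon
    (fewer than 3 distinct points, or all collinear); ``vertices`` then holds
    the distinct source points instead of a ring and ``area_km2`` is 0.
    """

    vertices: tuple[GeoPoint, ...]
    degenerate: bool = False
    area_km2: float = 0.0

    def contains(self, p: GeoPoint, tol_km: float = 1e-9) -> bool:
        """Inside-or-on test in the hull's own projection (non-degenerate only)."""
        if self.degenerate:
            return any(_close(p, v) for v in self.vertices)
        ring = self.vertices
        lat0 = sum(v.lat for v in ring[:-1]) / (len(ring) - 1)
        lon0 = sum(v.lon for v in ring[:-1]) / (len(ring) - 1)
        xy = _project(ring, lat0, lon0)
        px, py = _project([GeoPoint(*p)], lat0, lon0)[0]
        # signed distance to each CCW edge must be >= -tol
        for (x1, y1), (x2, y2) in zip(xy[:-1], xy[1:]):
            cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
            norm = math.hypot(x2 - x1, y2 - y1)
            if norm > 0 and cross / norm < -tol_km:
                return False
        return True


def _close(a: GeoPoint, b: GeoPoint, tol: float = 1e-12) -> bool:
    return abs(a.lat - b.lat) <= tol and abs(a.lon - b.lon) <= tol


def _project(points: Iterable[GeoPoint], lat0: float, lon0: float) -> list[tuple[float, float]]:
    """Equirectangular projection to km, centred on (lat0, lon0)."""
    k = math.pi / 180.0 * EARTH_RADIUS_KM
    c = math.cos(math.radians(lat0))
    return [((p.lon - lon0) * k * c, (p.lat - lat0) * k) for p in points]


def _unproject(xy: Iterable[tuple[float, float]], lat0: float, lon0: float) -> list[GeoPoint]:
    k = math.pi / 180.0 * EARTH_RADIUS_KM
    c = math.cos(math.radians(lat0))
    return [GeoPoint(lat0 + y / k, lon0 + x / (k * c)) for x, y in xy]


def convex_hull(points: Sequence[GeoPoint]) -> Polygon2D:
    """Convex hull of mission locations as a closed CCW ring of GeoPoints.

    Computed in a local equirectangular plane centred on the centroid of the
    input.  Degenerate inputs (fewer than 3 distinct points, or all collinear)
    return a ``Polygon2D`` flagged ``degenerate`` carrying the distinct points.
    """
    if len(points) == 0:
        raise InputError("convex_hull requires at least one point")
    pts = [GeoPoint(*p).validate() for p in points]
    distinct: list[GeoPoint] = []
    for p in pts:
        if not any(_close(p, q) for q in distinct):
            distinct.append(p)
    lat0 = sum(p.lat for p in pts) / len(pts)
    lon0 = sum(p.lon for p in pts) / len(pts)
    if len(distinct) < 3:
        return Polygon2D(tuple(sorted(distinct)), degenerate=True)
    hull = MultiPoint(_project(pts, lat0, lon0)).convex_hull
    if hull.geom_type != "Polygon":  # collinear input collapses to a LineString
        return Polygon2D(tuple(sorted(distinct)), degenerate=True)
    hull = orient(hull, sign=1.0)  # CCW exterior
    ring_xy = list(hull.exterior.coords)  # closed: first == last
    ring = _unproject(ring_xy, lat0, lon0)
    ring[-1] = ring[0]
    return Polygon2D(tuple(ring), degenerate=False, area_km2=float(hull.area))
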