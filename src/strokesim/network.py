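"""Road network routing: shortest travel times, hospital assignment, catchments.

The network is an undirected weighted graph; edge weight is the normal driving
time ``length_km / speed_kmh * 60`` minutes.  Emergency (lights-and-siren)
driving is modelled as a flat 20% reduction of the whole door-to-door time.
Shortest paths come from networkx's Dijkstra.  Mission scenes and hospitals
are snapped to their nearest node by great-circle distance; off-network access
time is taken as zero and large snap distances are logged.

Unreachable node pairs yield ``math.inf`` rather than raising, so callers can
flag missions as unroutable and keep an inclusion count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .exceptions import ConfigurationError, InputError, ValidationError
from .geodesy import GeoPoint, Polygon2D, convex_hull, great_circle_km, great_circle_km_vec

logger = logging.getLogger(__name__)

Capability = Literal["thrombolysis", "thrombectomy"]
UNREACHABLE = math.inf

#: snap distances beyond this are logged as suspicious (km)
SNAP_WARN_KM = 2.0


@dataclass(frozen=True)
class Hospital:
    """A receiving hospital.  Capability tiers are nested: every thrombectomy
    (university) hospital is also thrombolysis-capable."""

    id: str
    location: GeoPoint
    capability: Capability

    def __post_init__(self):
        if self.capability not in ("thrombolysis", "thrombectomy"):
            raise ValidationError(f"hospital {self.id}: unknown capability {self.capability!r}")
        self.location.validate()

    def satisfies(self, tier: Capability) -> bool:
        if tier == "thrombolysis":
            return True  # both tiers can give thrombolysis
        return self.capability == "thrombectomy"


@dataclass(frozen=True)
class HemsBase:
    """A helicopter EMS base."""

    id: str
    location: GeoPoint

    def __post_init__(self):
        self.location.validate()


def siren_drive_min(t_normal_min: float, reduction: float = 0.20) -> float:
    """Emergency driving time: normal time reduced by ``reduction`` (default 20%)."""
    if not (0.0 <= reduction < 1.0):
        raise ConfigurationError(f"siren reduction must be in [0, 1), got {reduction}")
    if t_normal_min < 0:
        raise InputError(f"drive time must be non-negative, got {t_normal_min}")
    return t_normal_min * (1.0 - reduction)


class RoadNetwork:
    """Undirected road graph with coordinates, built from node and edge lists.

    Parameters
    ----------
    nodes : mapping of node id -> GeoPoint
    edges : iterable of (u, v, length_km, speed_kmh)
    """

    def __init__(
        self,
        nodes: Mapping[str, GeoPoint],
        edges: Iterable[tuple[str, str, float, float]],
    ):
        if not nodes:
            raise InputError("road network has no nodes")
        self.nodes: dict[str, GeoPoint] = {
            str(k): GeoPoint(*v).validate() for k, v in nodes.items()
        }
        self.graph = nx.Graph()
        self.graph.add_nodes_from(self.nodes)
        self._edges: list[tuple[str, str, float, float]] = []
        for u, v, length_km, speed_kmh in edges:
            u, v = str(u), str(v)
            if u not in self.nodes or v not in self.nodes:
                raise ValidationError(f"edge ({u}, {v}) references an unknown node")
            if length_km <= 0 or speed_kmh <= 0:
                raise ValidationError(
                    f"edge ({u}, {v}): length and speed must be positive "
                    f"(got {length_km} km, {speed_kmh} km/h)"
                )
            t = length_km / speed_kmh * 60.0
            self.graph.add_edge(u, v, length_km=float(length_km),
                                speed_kmh=float(speed_kmh), time_min=t)
            self._edges.append((u, v, float(length_km), float(speed_kmh)))
        # snap index: nearest-by-great-circle == nearest-by-3D-chord on the sphere
        self._node_ids = np.array(sorted(self.nodes), dtype=object)
        lat = np.array([self.nodes[i].lat for i in self._node_ids])
        lon = np.array([self.nodes[i].lon for i in self._node_ids])
        self._node_lat, self._node_lon = lat, lon
        phi, lam = np.radians(lat), np.radians(lon)
        xyz = np.column_stack(
            [np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam), np.sin(phi)]
        )
        self._tree = cKDTree(xyz)
        self._times_cache: dict[str, dict[str, float]] = {}

    # -- basic queries ------------------------------------------------------

    @property
    def edges(self) -> list[tuple[str, str, float, float]]:
        return list(self._edges)

    def snap_to_node(self, p: GeoPoint) -> str:
        """Node nearest to ``p`` by great-circle distance; ties go to the
        lexicographically smallest node id."""
        p = GeoPoint(*p).validate()
        phi, lam = math.radians(p.lat), math.radians(p.lon)
        q = [math.cos(phi) * math.cos(lam), math.cos(phi) * math.sin(lam), math.sin(phi)]
        k = min(8, len(self._node_ids))
        dist, idx = self._tree.query(q, k=k)
        dist, idx = np.atleast_1d(dist), np.atleast_1d(idx)
        near = idx[np.isclose(dist, dist[0], rtol=0.0, atol=1e-12)]
        best = min(str(self._node_ids[i]) for i in near)
        d_km = great_circle_km(p, self.nodes[best])
        if d_km > SNAP_WARN_KM:
            logger.warning("point %s snapped %.2f km to node %s", tuple(p), d_km, best)
        return best

    def snap_many(self, lat, lon) -> np.ndarray:
        """Vectorised snap for arrays of coordinates; same tie-break contract."""
        phi, lam = np.radians(np.asarray(lat, float)), np.radians(np.asarray(lon, float))
        q = np.column_stack([np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam), np.sin(phi)])
        k = min(8, len(self._node_ids))
        dist, idx = self._tree.query(q, k=k)
        if k == 1:
            dist, idx = dist[:, None], idx[:, None]
        out = np.empty(len(q), dtype=object)
        for row in range(len(q)):
            near = idx[row][np.isclose(dist[row], dist[row][0], rtol=0.0, atol=1e-12)]
            out[row] = min(str(self._node_ids[i]) for i in near)
        return out

    def normal_drive_min(self, origin: str, dest: str) -> float:
        """Shortest normal driving time between two nodes, minutes.

        Returns ``math.inf`` for disconnected pairs (logged, not raised).
        """
        for n in (origin, dest):
            if n not in self.nodes:
                raise InputError(f"unknown node {n!r}")
        if origin == dest:
            return 0.0
        t = self.times_from(origin).get(dest, UNREACHABLE)
        if math.isinf(t):
            logger.info("no road path between %s and %s", origin, dest)
        return t

    def times_from(self, source: str) -> dict[str, float]:
        """All-destinations normal driving times from ``source`` (cached Dijkstra)."""
        if source not in self.nodes:
            raise InputError(f"unknown node {source!r}")
        if source not in self._times_cache:
            self._times_cache[source] = dict(
                nx.single_source_dijkstra_path_length(self.graph, source, weight="time_min")
            )
        return self._times_cache[source]

    def is_connected(self) -> bool:
        return nx.is_connected(self.graph)

    # -- hospital assignment ------------------------------------------------

    def nearest_hospital(
        self,
        scene: GeoPoint,
        tier: Capability,
        hospitals: Sequence[Hospital],
    ) -> tuple[Hospital | None, float]:
        """Hospital of the requested tier with the shortest siren-adjusted
        drive from the scene, plus that drive time in minutes.

        Ties break on the smallest hospital id; if no eligible hospital is
        reachable, returns ``(None, inf)`` so the mission can be flagged
        unroutable rather than crashing.
        """
        eligible = sorted((h for h in hospitals if h.satisfies(tier)), key=lambda h: h.id)
        if not eligible:
            raise InputError(f"no hospital satisfies tier {tier!r}")
        scene_node = self.snap_to_node(scene)
        best: Hospital | None = None
        best_t = UNREACHABLE
        for h in eligible:
            t = self.times_from(self.snap_to_node(h.location)).get(scene_node, UNREACHABLE)
            if t < best_t:  # strict: earlier (smaller) id wins ties
                best, best_t = h, t
        if best is None:
            return None, UNREACHABLE
        return best, siren_drive_min(best_t)

    def catchments(
        self,
        missions: Sequence,
        hospitals: Sequence[Hospital],
        tier: Capability,
    ) -> dict[str, Polygon2D]:
        """Convex-hull catchment per hospital from the missions it serves fastest.

        Missions are partitioned by :meth:`nearest_hospital`; each group's
        locations form one hull.  Groups with fewer than 3 distinct points
        yield degenerate (flagged) hulls.  Unroutable missions are skipped.
        """
        groups: dict[str, list[GeoPoint]] = {}
        for m in missions:
            h, t = self.nearest_hospital(m.location, tier, hospitals)
            if h is None or math.isinf(t):
                logger.info("mission %s unroutable for tier %s; excluded", m.id, tier)
                continue
            groups.setdefault(h.id, []).append(m.location)
        out = {}
        for hid in sorted(groups):
            hull = convex_hull(groups[hid])
            if hull.degenerate:
                logger.warning("catchment for hospital %s is degenerate (%d distinct points)",
                               hid, len(hull.vertices))
            out[hid] = hull
        return out
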