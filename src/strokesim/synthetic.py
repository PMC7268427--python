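"""Seeded generator for a synthetic country: hospitals, HEMS bases, roads, missions.

The generator emulates the statistical structure of one year of nationwide
stroke-suspected EMS dispatches in a Nordic-scale country (~20k missions,
a handful of university hospitals with thrombectomy capability nested inside
a larger set of thrombolysis-capable hospitals, a few helicopter bases, and
a strongly urban-clustered mission distribution over a large sparse area):

* Urban centers are placed uniformly in the extent with Zipf-like size
  weights; the road network is a trunk spanning tree over the centers plus
  short local spurs around each center and a coarse rural lattice, so it is
  connected by construction.
* Hospitals sit at the largest centers; the thrombectomy subset at the very
  largest (tiers are nested).  Bases are placed near thrombectomy hospitals
  with a deterministic offset.
* Mission locations are a mixture of truncated-Gaussian clusters at the
  centers (weight ``urban_fraction``) and a uniform background.  The four
  area classes are assigned from local mission density (k-nearest-neighbour
  estimate) cut at fixed multiples of the uniform mean density, so a fully
  clustered mixture produces no rural labels.
* First-ambulance response times are log-normal per area class, with larger
  medians and heavier tails in rural classes.

Everything is a pure function of the spec (seed included); two runs with the
same spec are identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .exceptions import ConfigurationError
from .geodesy import EARTH_RADIUS_KM, GeoPoint
from .network import HemsBase, Hospital, RoadNetwork
from .scenarios import AREA_TYPES, Mission, World

_KM_PER_DEG = math.pi / 180.0 * EARTH_RADIUS_KM


@dataclass(frozen=True)
class RegionSpec:
    """Parameters of the synthetic region.

    Defaults draw a country of roughly Nordic extent (~8° x 8° around 64°N,
    ~350,000 km2) with 30 urban centers, 20 thrombolysis hospitals of which 5
    (the largest centers) offer thrombectomy, 6 HEMS bases and 20,000
    missions, three quarters of them urban-clustered.  Response-time
    log-normals give medians of about 7 / 9 / 14 / 20 minutes from core urban
    to other rural, with heavier right tails in the rural classes.
    """

    seed: int = 0
    extent: tuple[float, float, float, float] = (60.0, 68.0, 22.0, 30.0)  # lat0,lat1,lon0,lon1
    n_urban_centers: int = 30
    n_hospitals_thrombolysis: int = 20
    n_hospitals_thrombectomy: int = 5
    n_bases: int = 6
    n_missions: int = 20_000
    urban_fraction: float = 0.75
    #: per-area-class log-normal parameters of response_min: {area: (mu, sigma)}
    response_lognorm: dict = field(default_factory=lambda: {
        "core_urban": (math.log(7.0), 0.40),
        "other_urban": (math.log(9.0), 0.45),
        "dispersed_settlement": (math.log(14.0), 0.50),
        "other_rural": (math.log(20.0), 0.55),
    })
    #: km/h for trunk (inter-city), regional (connector/lattice) and local roads
    speed_trunk_kmh: float = 100.0
    speed_regional_kmh: float = 80.0
    speed_local_kmh: float = 40.0
    #: std dev of urban mission clusters, km (truncated at 2.5 sigma)
    cluster_sigma_km: float = 5.0
    #: area-class cuts on local density relative to the uniform mean density:
    #: core_urban above the first cut, then other_urban, dispersed_settlement,
    #: other_rural below the last
    density_cuts: tuple[float, float, float] = (80.0, 10.0, 0.8)
    #: neighbours used in the k-NN density estimate
    density_k: int = 10
    #: rural lattice spacing, degrees
    lattice_step_deg: float = 0.8
    #: road winding factor: road length = winding * great-circle distance
    winding: float = 1.3

    def __post_init__(self):
        if self.n_hospitals_thrombectomy > self.n_hospitals_thrombolysis:
            raise ConfigurationError("thrombectomy hospitals must be a subset of "
                                     "thrombolysis hospitals")
        if self.n_hospitals_thrombolysis > self.n_urban_centers:
            raise ConfigurationError("more hospitals than urban centers")
        for name in ("n_urban_centers", "n_hospitals_thrombolysis",
                     "n_hospitals_thrombectomy", "n_bases"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_missions < 0:
            raise ConfigurationError("n_missions must be non-negative")
        if not (0.0 < self.urban_fraction <= 1.0):
            raise ConfigurationError("urban_fraction must be in (0, 1]")
        lat0, lat1, lon0, lon1 = self.extent
        if not (lat0 < lat1 and lon0 < lon1):
            raise ConfigurationError("extent must be (lat0 < lat1, lon0 < lon1)")
        missing = set(AREA_TYPES) - set(self.response_lognorm)
        if missing:
            raise ConfigurationError(f"response_lognorm missing classes: {sorted(missing)}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["extent"] = list(self.extent)
        d["density_cuts"] = list(self.density_cuts)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RegionSpec":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown region spec keys: {sorted(unknown)}")
        d = dict(d)
        if "extent" in d:
            d["extent"] = tuple(d["extent"])
        if "density_cuts" in d:
            d["density_cuts"] = tuple(d["density_cuts"])
        if "response_lognorm" in d:
            d["response_lognorm"] = {k: tuple(v) for k, v in d["response_lognorm"].items()}
        return cls(**d)


def _center_weights(n: int) -> np.ndarray:
    """Zipf-like center size weights, largest first, summing to 1."""
    w = 1.0 / np.arange(1, n + 1)
    return w / w.sum()


def _sample_centers(spec: RegionSpec, rng: np.random.Generator) -> np.ndarray:
    """Center coordinates (lat, lon), with a minimum mutual separation."""
    lat0, lat1, lon0, lon1 = spec.extent
    min_sep_deg = 0.15 * min(lat1 - lat0, lon1 - lon0) / max(1.0, math.sqrt(spec.n_urban_centers))
    centers: list[tuple[float, float]] = []
    for _ in range(10_000):
        if len(centers) == spec.n_urban_centers:
            break
        lat = rng.uniform(lat0 + 0.05 * (lat1 - lat0), lat1 - 0.05 * (lat1 - lat0))
        lon = rng.uniform(lon0 + 0.05 * (lon1 - lon0), lon1 - 0.05 * (lon1 - lon0))
        if all(math.hypot(lat - a, lon - b) >= min_sep_deg for a, b in centers):
            centers.append((lat, lon))
    if len(centers) < spec.n_urban_centers:
        raise ConfigurationError("could not place urban centers with minimum separation")
    return np.array(centers)


def _gc_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    from .geodesy import great_circle_km
    return great_circle_km(GeoPoint(*a), GeoPoint(*b))


def generate_region(spec: RegionSpec) -> World:
    """Build the synthetic world: road network, hospitals, HEMS bases.

    Fully deterministic in ``spec`` (including the seed); the road graph is
    connected by construction (spanning tree over centers, spurs and lattice
    all attach to it).
    """
    rng = np.random.default_rng(spec.seed)
    centers = _sample_centers(spec, rng)
    n_c = len(centers)
    lat0, lat1, lon0, lon1 = spec.extent

    nodes: dict[str, GeoPoint] = {}
    edges: list[tuple[str, str, float, float]] = []
    center_ids = [f"C{i:02d}" for i in range(n_c)]
    for cid, (la, lo) in zip(center_ids, centers):
        nodes[cid] = GeoPoint(la, lo)

    # local spurs: 4 short urban-street nodes around each center
    spur_km = 3.0
    for i, cid in enumerate(center_ids):
        la, lo = centers[i]
        coslat = math.cos(math.radians(la))
        for j, (dy, dx) in enumerate([(1, 0), (-1, 0), (0, 1), (0, -1)]):
            sid = f"{cid}s{j}"
            nodes[sid] = GeoPoint(la + dy * spur_km / _KM_PER_DEG,
                                  lo + dx * spur_km / (_KM_PER_DEG * coslat))
            edges.append((cid, sid, spur_km * 1.2, spec.speed_local_kmh))

    # trunk roads: minimum spanning tree over centers + 2-nearest-neighbour links
    dmat = np.array([[_gc_km(tuple(a), tuple(b)) for b in centers] for a in centers])
    in_tree = {0}
    while len(in_tree) < n_c:
        best = None
        for i in sorted(in_tree):
            for j in range(n_c):
                if j in in_tree:
                    continue
                if best is None or dmat[i, j] < best[0]:
                    best = (dmat[i, j], i, j)
        _, i, j = best
        in_tree.add(j)
        edges.append((center_ids[i], center_ids[j], dmat[i, j] * spec.winding,
                      spec.speed_trunk_kmh))
    seen = {tuple(sorted((u, v))) for u, v, *_ in edges}
    for i in range(n_c):
        for j in np.argsort(dmat[i])[1:3]:
            key = tuple(sorted((center_ids[i], center_ids[int(j)])))
            if key not in seen:
                seen.add(key)
                edges.append((center_ids[i], center_ids[int(j)],
                              dmat[i, int(j)] * spec.winding, spec.speed_trunk_kmh))

    # coarse rural lattice attached to its nearest centers
    lats = np.arange(lat0 + spec.lattice_step_deg / 2, lat1, spec.lattice_step_deg)
    lons = np.arange(lon0 + spec.lattice_step_deg / 2, lon1, spec.lattice_step_deg)
    for a, la in enumerate(lats):
        for b, lo in enumerate(lons):
            nid = f"R{a:02d}_{b:02d}"
            nodes[nid] = GeoPoint(float(la), float(lo))
            if a > 0:
                prev = f"R{a - 1:02d}_{b:02d}"
                edges.append((prev, nid, _gc_km(tuple(nodes[prev]), (la, lo)) * spec.winding,
                              spec.speed_regional_kmh))
            if b > 0:
                prev = f"R{a:02d}_{b - 1:02d}"
                edges.append((prev, nid, _gc_km(tuple(nodes[prev]), (la, lo)) * spec.winding,
                              spec.speed_regional_kmh))
    for i, cid in enumerate(center_ids):
        la, lo = centers[i]
        a = int(np.clip(round((la - lats[0]) / spec.lattice_step_deg), 0, len(lats) - 1))
        b = int(np.clip(round((lo - lons[0]) / spec.lattice_step_deg), 0, len(lons) - 1))
        rid = f"R{a:02d}_{b:02d}"
        d = max(_gc_km((la, lo), tuple(nodes[rid])), 0.5)
        edges.append((cid, rid, d * spec.winding, spec.speed_regional_kmh))

    net = RoadNetwork(nodes, edges)

    # hospitals at the largest centers (centers are ordered by size weight)
    hospitals = []
    for i in range(spec.n_hospitals_thrombolysis):
        cap = "thrombectomy" if i < spec.n_hospitals_thrombectomy else "thrombolysis"
        hospitals.append(Hospital(f"H{i:02d}", GeoPoint(*centers[i]), cap))

    # bases near thrombectomy hospitals (then next-largest centers), offset ~15 km
    bases = []
    for i in range(spec.n_bases):
        la, lo = centers[i % n_c]
        ang = rng.uniform(0, 2 * math.pi)
        off_km = rng.uniform(8.0, 20.0)
        bla = la + off_km * math.sin(ang) / _KM_PER_DEG
        blo = lo + off_km * math.cos(ang) / (_KM_PER_DEG * math.cos(math.radians(la)))
        bases.append(HemsBase(f"B{i:02d}", GeoPoint(bla, blo)))

    return World(hospitals=tuple(hospitals), bases=tuple(bases), network=net)


def generate_missions(spec: RegionSpec, world: World) -> list[Mission]:
    """Draw the mission set for a generated world.

    Locations come from the cluster/background mixture; area classes from the
    k-NN density of the drawn locations relative to the uniform mean density;
    response times from the per-class log-normals.  Deterministic in ``spec``.
    """
    rng = np.random.default_rng(spec.seed + 1)  # independent of region layout
    n = spec.n_missions
    if n == 0:
        return []
    lat0, lat1, lon0, lon1 = spec.extent
    # re-derive center coordinates deterministically from the region seed
    centers = _sample_centers(spec, np.random.default_rng(spec.seed))
    weights = _center_weights(len(centers))

    is_urban = rng.random(n) < spec.urban_fraction
    which = rng.choice(len(centers), size=n, p=weights)
    # truncated (2.5 sigma) Gaussian offsets in km
    off = rng.normal(0.0, spec.cluster_sigma_km, size=(n, 2))
    norm = np.linalg.norm(off, axis=1)
    cap = 2.5 * spec.cluster_sigma_km
    over = norm > cap
    off[over] *= (cap / norm[over])[:, None]
    clat = centers[which, 0] + off[:, 0] / _KM_PER_DEG
    clon = centers[which, 1] + off[:, 1] / (_KM_PER_DEG * np.cos(np.radians(centers[which, 0])))
    ulat = rng.uniform(lat0, lat1, size=n)
    ulon = rng.uniform(lon0, lon1, size=n)
    lat = np.where(is_urban, clat, ulat)
    lon = np.where(is_urban, clon, ulon)
    lat = np.clip(lat, -90.0, 90.0)
    lon = np.clip(lon, -180.0, 180.0)

    area = classify_area(lat, lon, spec)
    resp = np.empty(n)
    for cls in AREA_TYPES:
        mask = area == cls
        mu, sigma = spec.response_lognorm[cls]
        resp[mask] = rng.lognormal(mu, sigma, size=int(mask.sum()))
    resp = np.maximum(resp, 0.0)

    return [
        Mission(f"M{i:06d}", GeoPoint(float(lat[i]), float(lon[i])),
                str(area[i]), float(resp[i]))
        for i in range(n)
    ]


def classify_area(lat, lon, spec: RegionSpec) -> np.ndarray:
    """Assign the four area classes from local mission density.

    Density is estimated per mission as ``k / (pi * d_k^2)`` with ``d_k`` the
    distance to the k-th nearest other mission (projected km), then compared
    to the uniform mean density ``n / extent_area`` at the fixed relative
    cuts in ``spec.density_cuts``.
    """
    lat = np.asarray(lat, float)
    lon = np.asarray(lon, float)
    n = len(lat)
    lat0, lat1, lon0, lon1 = spec.extent
    latc = (lat0 + lat1) / 2.0
    x = lon * _KM_PER_DEG * math.cos(math.radians(latc))
    y = lat * _KM_PER_DEG
    area_km2 = ((lat1 - lat0) * _KM_PER_DEG) * ((lon1 - lon0) * _KM_PER_DEG
                                                * math.cos(math.radians(latc)))
    lam_uniform = n / area_km2
    k = min(spec.density_k, n - 1)
    if k < 1:
        return np.array(["core_urban"] * n, dtype=object)
    tree = cKDTree(np.column_stack([x, y]))
    dk = tree.query(np.column_stack([x, y]), k=k + 1)[0][:, -1]  # +1: self at distance 0
    dk = np.maximum(dk, 1e-6)
    ratio = (k / (math.pi * dk ** 2)) / lam_uniform
    c1, c2, c3 = spec.density_cuts
    out = np.full(n, "other_rural", dtype=object)
    out[ratio >= c3] = "dispersed_settlement"
    out[ratio >= c2] = "other_urban"
    out[ratio >= c1] = "core_urban"
    return out
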