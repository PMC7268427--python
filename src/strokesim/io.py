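"""File formats, run configuration and the end-to-end pipeline.

Formats
-------
* Road network: ``nodes.csv`` (``id,lat,lon``) + ``edges.csv``
  (``u,v,length_km,speed_kmh``).
* Hospitals / HEMS bases: GeoJSON FeatureCollections of Point features;
  hospitals carry ``id`` and ``capability`` properties, bases carry ``id``.
  GeoJSON coordinates are ``[lon, lat]`` per the standard; CSV columns are
  named ``lat``/``lon`` explicitly.
* Missions: CSV ``id,lat,lon,area_type,response_min``.
* Outputs: per-mission CSV, tidy summary CSVs, break-even CSVs, catchment and
  fastest-method GeoJSON, a text rendering of the tables, the resolved
  configuration (provenance), and an inclusion-accounting JSON.

The generated and the read formats are identical, so synthetic and real
inputs are interchangeable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from .exceptions import ConfigurationError, ValidationError
from .geodesy import GeoPoint, Polygon2D
from .network import HemsBase, Hospital, RoadNetwork
from .scenarios import AREA_TYPES, Mission, ScenarioParams, World

logger = logging.getLogger(__name__)


# -- GeoJSON helpers ---------------------------------------------------------

def _point_feature(p: GeoPoint, properties: dict) -> dict:
    return {"type": "Feature", "properties": properties,
            "geometry": {"type": "Point", "coordinates": [p.lon, p.lat]}}


def _read_point_features(path: Path) -> list[tuple[GeoPoint, dict]]:
    with open(path) as fh:
        try:
            gj = json.load(fh)
        except json.JSONDecodeError as e:
            raise ValidationError(f"{path}: not valid JSON ({e})") from e
    if gj.get("type") != "FeatureCollection":
        raise ValidationError(f"{path}: expected a GeoJSON FeatureCollection")
    out = []
    for i, feat in enumerate(gj.get("features", [])):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Point":
            raise ValidationError(f"{path}: feature {i} is not a Point")
        lon, lat = geom["coordinates"][:2]
        out.append((GeoPoint(float(lat), float(lon)), feat.get("properties") or {}))
    return out


def write_geojson(path: Path, features: list[dict]) -> None:
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)
        fh.write("\n")


# -- world -------------------------------------------------------------------

def read_world(nodes_csv, edges_csv, hospitals_geojson, bases_geojson) -> World:
    """Read and validate a world; raises ``ValidationError`` on integrity errors."""
    nodes_df = pd.read_csv(nodes_csv, dtype={"id": str}, float_precision="round_trip")
    for col in ("id", "lat", "lon"):
        if col not in nodes_df.columns:
            raise ValidationError(f"{nodes_csv}: missing column {col!r}")
    nodes = {r.id: GeoPoint(float(r.lat), float(r.lon)) for r in nodes_df.itertuples()}
    edges_df = pd.read_csv(edges_csv, dtype={"u": str, "v": str},
                           float_precision="round_trip")
    for col in ("u", "v", "length_km", "speed_kmh"):
        if col not in edges_df.columns:
            raise ValidationError(f"{edges_csv}: missing column {col!r}")
    edges = [(r.u, r.v, float(r.length_km), float(r.speed_kmh))
             for r in edges_df.itertuples()]
    net = RoadNetwork(nodes, edges)

    hospitals = []
    for p, props in _read_point_features(Path(hospitals_geojson)):
        if "id" not in props or "capability" not in props:
            raise ValidationError(f"{hospitals_geojson}: hospital feature needs "
                                  "'id' and 'capability' properties")
        hospitals.append(Hospital(str(props["id"]), p, str(props["capability"])))
    bases = []
    for p, props in _read_point_features(Path(bases_geojson)):
        if "id" not in props:
            raise ValidationError(f"{bases_geojson}: base feature needs an 'id' property")
        bases.append(HemsBase(str(props["id"]), p))
    world = World(tuple(hospitals), tuple(bases), net)
    logger.info("world: %d nodes, %d edges, %d hospitals (%d thrombectomy), %d bases",
                len(nodes), len(edges), len(hospitals),
                sum(h.capability == "thrombectomy" for h in hospitals), len(bases))
    return world


def write_world(world: World, outdir) -> dict[str, Path]:
    """Write a world in the same formats :func:`read_world` reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "nodes": outdir / "nodes.csv", "edges": outdir / "edges.csv",
        "hospitals": outdir / "hospitals.geojson", "bases": outdir / "bases.geojson",
    }
    net = world.network
    pd.DataFrame(
        [{"id": k, "lat": p.lat, "lon": p.lon} for k, p in sorted(net.nodes.items())]
    ).to_csv(paths["nodes"], index=False)
    pd.DataFrame(
        [{"u": u, "v": v, "length_km": l, "speed_kmh": s} for u, v, l, s in net.edges]
    ).to_csv(paths["edges"], index=False)
    write_geojson(paths["hospitals"], [
        _point_feature(h.location, {"id": h.id, "capability": h.capability})
        for h in world.hospitals])
    write_geojson(paths["bases"], [
        _point_feature(b.location, {"id": b.id}) for b in world.bases])
    return paths


# -- missions ----------------------------------------------------------------

def read_missions(path) -> list[Mission]:
    df = pd.read_csv(path, dtype={"id": str, "area_type": str},
                     float_precision="round_trip")
    for col in ("id", "lat", "lon", "area_type", "response_min"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    return [Mission(r.id, GeoPoint(float(r.lat), float(r.lon)), r.area_type,
                    float(r.response_min))
            for r in df.itertuples()]


def write_missions(missions, path) -> Path:
    path = Path(path)
    pd.DataFrame([{"id": m.id, "lat": m.location.lat, "lon": m.location.lon,
                   "area_type": m.area_type, "response_min": m.response_min}
                  for m in missions]).to_csv(path, index=False)
    return path


# -- polygons / result exports -----------------------------------------------

def catchments_to_features(catchments: dict[str, Polygon2D],
                           mission_counts: dict[str, int] | None = None) -> list[dict]:
    """Catchment hulls as GeoJSON Polygon features; degenerate hulls are
    skipped with a warning (no zero-area rings are fabricated)."""
    feats = []
    for hid, hull in sorted(catchments.items()):
        if hull.degenerate:
            logger.warning("hospital %s: degenerate catchment (%d points) not exported",
                           hid, len(hull.vertices))
            continue
        ring = [[v.lon, v.lat] for v in hull.vertices]
        feats.append({
            "type": "Feature",
            "properties": {"hospital_id": hid, "area_km2": hull.area_km2,
                           "n_missions": (mission_counts or {}).get(hid),
                           "projection": "equirectangular-local"},
            "geometry": {"type": "Polygon", "coordinates": [ring]},
        })
    return feats


def fastest_method_features(results: pd.DataFrame) -> list[dict]:
    """Per-mission points carrying the fastest-method labels (thematic-map
    analogue)."""
    feats = []
    for r in results.itertuples():
        if not r.routable:
            continue
        feats.append(_point_feature(GeoPoint(r.lat, r.lon), {
            "mission_id": r.mission_id, "area_type": r.area_type,
            "fastest_simultaneous": r.fastest_simultaneous,
            "fastest_after_eval": r.fastest_after_eval,
            "saved_s3": round(float(r.saved_s3), 3),
            "saved_s4": round(float(r.saved_s4), 3),
        }))
    return feats


# -- run configuration -------------------------------------------------------

_CONFIG_KEYS = {"hospitals", "bases", "nodes", "edges", "missions", "outdir",
                "params", "seed", "report"}
_REPORT_KEYS = {"bin_width_min", "interval", "make_plots"}


@dataclasses.dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    hospitals: str
    bases: str
    nodes: str
    edges: str
    missions: str
    outdir: str
    params: ScenarioParams = dataclasses.field(default_factory=ScenarioParams)
    seed: int = 0
    bin_width_min: float = 10.0
    interval: str = "percentile"
    make_plots: bool = False

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise ConfigurationError(f"{path}: unknown config keys {sorted(unknown)}")
        report = raw.pop("report", {}) or {}
        unknown = set(report) - _REPORT_KEYS
        if unknown:
            raise ConfigurationError(f"{path}: unknown report keys {sorted(unknown)}")
        params = ScenarioParams.from_dict(raw.pop("params", {}) or {})
        missing = {"hospitals", "bases", "nodes", "edges", "missions", "outdir"} - set(raw)
        if missing:
            raise ConfigurationError(f"{path}: missing config keys {sorted(missing)}")
        return cls(params=params, **{k: raw[k] for k in raw}, **report)

    def to_dict(self) -> dict:
        return {
            "hospitals": self.hospitals, "bases": self.bases, "nodes": self.nodes,
            "edges": self.edges, "missions": self.missions, "outdir": self.outdir,
            "seed": self.seed, "params": self.params.to_dict(),
            "report": {"bin_width_min": self.bin_width_min, "interval": self.interval,
                       "make_plots": self.make_plots},
        }


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Read inputs, simulate the four scenarios, and write every artifact.

    Returns a map of artifact name to path.  Deterministic: identical inputs
    and configuration produce byte-identical outputs.
    """
    from . import stats
    from .model import StrokeTransportModel

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("strokesim")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        world = read_world(config.nodes, config.edges, config.hospitals, config.bases)
        missions = read_missions(config.missions)
        model = StrokeTransportModel(missions, world, config.params)
        res = model.fit()

        paths: dict[str, Path] = {}
        paths["per_mission"] = outdir / "mission_results.csv"
        res.per_mission.to_csv(paths["per_mission"], index=False)

        tg = res.table_ground(interval=config.interval)
        ts = res.table_saved("simultaneous", interval=config.interval)
        te = res.table_saved("after_eval", interval=config.interval)
        paths["table_ground"] = outdir / "table_ground.csv"
        tg.to_csv(paths["table_ground"], index=False)
        paths["table_saved_simultaneous"] = outdir / "table_saved_simultaneous.csv"
        ts.to_csv(paths["table_saved_simultaneous"], index=False)
        paths["table_saved_after_eval"] = outdir / "table_saved_after_eval.csv"
        te.to_csv(paths["table_saved_after_eval"], index=False)
        paths["tables_txt"] = outdir / "tables.txt"
        paths["tables_txt"].write_text(stats.render_tables_text(tg, ts, te))

        for mode in ("simultaneous", "after_eval"):
            curve = res.breakeven(mode, bin_width_min=config.bin_width_min)
            p = outdir / f"breakeven_{mode}.csv"
            curve.to_frame().to_csv(p, index=False)
            paths[f"breakeven_{mode}"] = p
            logger.info("break-even threshold (%s): %s min", mode, curve.threshold_min)
            if config.make_plots:
                pp = outdir / f"breakeven_{mode}.png"
                res.plot_breakeven(mode, bin_width_min=config.bin_width_min, path=pp)
                paths[f"breakeven_{mode}_png"] = pp

        for tier in ("thrombolysis", "thrombectomy"):
            hulls, counts = res.catchments(tier)
            p = outdir / f"catchments_{tier}.geojson"
            write_geojson(p, catchments_to_features(hulls, counts))
            paths[f"catchments_{tier}"] = p

        paths["fastest_method"] = outdir / "fastest_method.geojson"
        write_geojson(paths["fastest_method"], fastest_method_features(res.per_mission))

        acc = res.inclusion
        paths["inclusion"] = outdir / "inclusion.json"
        paths["inclusion"].write_text(json.dumps(acc, indent=1) + "\n")
        logger.info("missions: total %(n_total)d, included %(n_included)d, "
                    "excluded %(n_excluded)d", acc)

        paths["config"] = outdir / "resolved_config.yaml"
        with open(paths["config"], "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
        return paths
    finally:
        root.removeHandler(handler)
        handler.close()
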