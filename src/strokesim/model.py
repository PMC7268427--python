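"""Model/results interface over the scenario simulation.

`StrokeTransportModel` bundles a mission set, a world (hospitals, HEMS bases,
road network) and the timing parameters; :meth:`StrokeTransportModel.fit`
evaluates all four transport scenarios for every mission and returns a
:class:`TransportResults` carrying the per-mission table plus the reporting
layer (stratified tables, break-even curves, catchments, summary text).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from . import stats
from .exceptions import InputError
from .geodesy import GeoPoint, Polygon2D
from .network import Capability
from .scenarios import (Mission, ScenarioParams, World, evaluate_missions)


def catchments_from_results(per_mission: pd.DataFrame, tier: Capability
                            ) -> tuple[dict[str, Polygon2D], dict[str, int]]:
    """Group routable missions by their fastest hospital of the tier and hull
    each group; returns (hulls, per-hospital mission counts)."""
    from .geodesy import convex_hull

    dest_col = "dest_s1" if tier == "thrombolysis" else "dest_s2"
    routable = per_mission[per_mission["routable"].astype(bool)]
    groups: dict[str, list[GeoPoint]] = {}
    for r in routable.itertuples():
        groups.setdefault(getattr(r, dest_col), []).append(GeoPoint(r.lat, r.lon))
    hulls = {hid: convex_hull(pts) for hid, pts in sorted(groups.items())}
    counts = {hid: len(pts) for hid, pts in groups.items()}
    return hulls, counts


class StrokeTransportModel:
    """Four-scenario pre-hospital transport model for a set of missions.

    Parameters
    ----------
    missions : sequence of Mission
    world : World
        Hospitals (tiered), HEMS bases and the road network.
    params : ScenarioParams, optional
        Timing constants; defaults are the model's reference values
        (220 km/h, 6 min en-route, 26 min on-scene, 10 min unload, 20%
        siren reduction).
    """

    def __init__(self, missions: Sequence[Mission], world: World,
                 params: ScenarioParams | None = None):
        self.missions = list(missions)
        self.world = world
        self.params = params or ScenarioParams()

    @classmethod
    def from_files(cls, nodes, edges, hospitals, bases, missions,
                   params: ScenarioParams | None = None) -> "StrokeTransportModel":
        """Build a model from the standard CSV/GeoJSON input files."""
        from .io import read_missions, read_world
        world = read_world(nodes, edges, hospitals, bases)
        return cls(read_missions(missions), world, params)

    def fit(self) -> "TransportResults":
        """Evaluate every mission under scenarios S1-S4."""
        table = evaluate_missions(self.missions, self.world, self.params)
        return TransportResults(self, table)


class TransportResults:
    """Per-mission scenario times and the derived reporting layer."""

    def __init__(self, model: StrokeTransportModel, per_mission: pd.DataFrame):
        self.model = model
        self.per_mission = per_mission

    # -- accounting ---------------------------------------------------------

    @property
    def inclusion(self) -> dict[str, int]:
        """Mission inclusion accounting: ``n_total = n_included + n_excluded``."""
        n_total = int(len(self.per_mission))
        n_inc = int(self.per_mission["routable"].astype(bool).sum())
        return {"n_total": n_total, "n_included": n_inc, "n_excluded": n_total - n_inc}

    @property
    def routable(self) -> pd.DataFrame:
        return self.per_mission[self.per_mission["routable"].astype(bool)]

    # -- tables and curves --------------------------------------------------

    def table_ground(self, interval: str = "percentile") -> pd.DataFrame:
        return stats.table_ground(self.per_mission, interval=interval)

    def table_saved(self, mode: str = "simultaneous",
                    interval: str = "percentile") -> pd.DataFrame:
        return stats.table_saved(self.per_mission, mode=mode, interval=interval)

    def breakeven(self, mode: str = "simultaneous",
                  bin_width_min: float = 10.0) -> stats.BreakEvenCurve:
        return stats.breakeven(self.per_mission, mode=mode, bin_width_min=bin_width_min)

    def catchments(self, tier: Capability = "thrombolysis"
                   ) -> tuple[dict[str, Polygon2D], dict[str, int]]:
        """Convex-hull catchments and per-hospital mission counts for a tier."""
        return catchments_from_results(self.per_mission, tier)

    # -- presentation -------------------------------------------------------

    def summary(self, interval: str = "percentile") -> str:
        """Human-readable run summary: inclusion, pooled medians, tables."""
        acc = self.inclusion
        routable = self.routable
        lines = [
            "Pre-hospital stroke transport simulation",
            "=" * 48,
            f"missions: {acc['n_total']} total, {acc['n_included']} routable "
            f"({100.0 * acc['n_included'] / max(acc['n_total'], 1):.1f}%), "
            f"{acc['n_excluded']} excluded",
        ]
        if len(routable):
            for col, label in (("t1", "ground to thrombolysis-capable (S1)"),
                               ("t2", "ground to thrombectomy-capable (S2)"),
                               ("t3", "helicopter, simultaneous dispatch (S3)"),
                               ("t4", "helicopter, dispatch after evaluation (S4)")):
                lo, med, hi = stats.percentile_interval(routable[col].to_numpy())
                lines.append(f"  {label}: median {med:.1f} min ({lo:.1f}-{hi:.1f})")
            fastest = routable[["t2", "t3"]].min(axis=1)
            lines.append(f"  fastest of S2/S3: mean {fastest.mean():.2f} min "
                         f"(median {fastest.median():.2f})")
            for mode in ("simultaneous", "after_eval"):
                curve = self.breakeven(mode)
                thr = ("none" if curve.threshold_min is None
                       else f"{curve.threshold_min:.0f} min ground transport leg")
                lines.append(f"  break-even ({mode}): {thr}")
        lines.append("")
        lines.append(stats.render_tables_text(
            self.table_ground(interval=interval),
            self.table_saved("simultaneous", interval=interval),
            self.table_saved("after_eval", interval=interval)))
        return "\n".join(lines)

    def plot_breakeven(self, mode: str = "simultaneous", bin_width_min: float = 10.0,
                       path: str | Path | None = None):
        """Bar chart of the helicopter-fastest fraction by ground transport leg."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        curve = self.breakeven(mode, bin_width_min=bin_width_min)
        df = curve.to_frame()
        fig, ax = plt.subplots(figsize=(7, 4))
        ax.bar(df["bin_mid"], df["fraction"], width=0.9 * bin_width_min,
               color="#3a7ca5", label="helicopter fastest")
        ax.axhline(0.5, color="grey", ls="--", lw=1)
        if curve.threshold_min is not None:
            ax.axvline(curve.threshold_min, color="firebrick", ls=":",
                       label=f"break-even ≈ {curve.threshold_min:.0f} min")
        ax.set_xlabel("ground transport leg to thrombectomy hospital (min)")
        ax.set_ylabel("fraction of missions where helicopter is fastest")
        ax.set_title(f"HEMS break-even curve ({mode} dispatch)")
        ax.set_ylim(0, 1)
        ax.legend(loc="lower right")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
            return path
        return fig
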