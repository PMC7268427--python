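"""Stratified reporting layer: median tables, time-saved tables, break-even curves.

All "95% intervals" here are 2.5th–97.5th percentiles of the per-mission time
distribution (reference intervals), computed with type-7 linear-interpolation
quantiles; an interval that wide describes between-mission spread, not the
sampling uncertainty of the median.  A bootstrap CI of the median is available
behind ``interval="bootstrap"`` for users who want the literal reading.

Strata are the four area classes plus a pooled ``Total`` row; the Total row
is always a recomputation over the pooled missions, so stratum counts sum to
it by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputError
from .scenarios import AREA_TYPES

STRATA = AREA_TYPES + ("Total",)
Mode = Literal["simultaneous", "after_eval"]

_MODE_COLS = {"simultaneous": ("saved_s3", "fastest_simultaneous"),
              "after_eval": ("saved_s4", "fastest_after_eval")}


def percentile_interval(
    values: Sequence[float],
    probs: tuple[float, float, float] = (2.5, 50.0, 97.5),
) -> tuple[float, float, float]:
    """(lower, median, upper) percentiles with linear interpolation (type 7)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InputError("percentile_interval needs a non-empty input")
    lo, med, hi = np.percentile(arr, probs, method="linear")
    return float(lo), float(med), float(hi)


def bootstrap_median_ci(
    values: Sequence[float], n_boot: int = 2000, seed: int = 0, level: float = 95.0
) -> tuple[float, float, float]:
    """Percentile-bootstrap CI of the median: (lower, median, upper)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InputError("bootstrap_median_ci needs a non-empty input")
    rng = np.random.default_rng(seed)
    meds = np.median(rng.choice(arr, size=(n_boot, arr.size), replace=True), axis=1)
    alpha = (100.0 - level) / 2.0
    lo, hi = np.percentile(meds, [alpha, 100.0 - alpha])
    return float(lo), float(np.median(arr)), float(hi)


def _interval(values: np.ndarray, interval: str, seed: int = 0):
    if interval == "percentile":
        return percentile_interval(values)
    if interval == "bootstrap":
        return bootstrap_median_ci(values, seed=seed)
    raise ConfigurationError(f"unknown interval mode {interval!r}")


def _routable(results: pd.DataFrame) -> pd.DataFrame:
    return results[results["routable"].astype(bool)]


def _strata_frames(df: pd.DataFrame):
    for stratum in STRATA:
        yield stratum, (df if stratum == "Total" else df[df["area_type"] == stratum])


def table_ground(results: pd.DataFrame, interval: str = "percentile") -> pd.DataFrame:
    """Ground-transport-only summary per area type and Total.

    One row per stratum: mission count, median (lower, upper) of the total
    pre-hospital time to the nearest thrombolysis-capable (``t1``) and to the
    nearest thrombectomy-capable hospital (``t2``), and the subgroup whose
    time would increase under direct-to-thrombectomy transport
    (``delay_increase > 0``): its count, share of the stratum, and the
    median (lower, upper) of the increase.
    """
    df = _routable(results)
    rows = []
    for stratum, sub in _strata_frames(df):
        row: dict = {"stratum": stratum, "n": int(len(sub))}
        if len(sub):
            for col, label in (("t1", "lysis"), ("t2", "thrombectomy")):
                lo, med, hi = _interval(sub[col].to_numpy(), interval)
                row.update({f"{label}_median": med, f"{label}_lower": lo, f"{label}_upper": hi})
            inc = sub[sub["delay_increase"] > 0]
            row["increase_n"] = int(len(inc))
            row["increase_pct"] = 100.0 * len(inc) / len(sub)
            if len(inc):
                lo, med, hi = _interval(inc["delay_increase"].to_numpy(), interval)
                row.update({"increase_median": med, "increase_lower": lo, "increase_upper": hi})
        rows.append(row)
    return pd.DataFrame(rows)


def table_saved(
    results: pd.DataFrame, mode: Mode = "simultaneous", interval: str = "percentile"
) -> pd.DataFrame:
    """Helicopter time-saved summary per stratum.

    Per stratum: missions where the helicopter is strictly faster than direct
    ground transport to thrombectomy (count and share), the median (lower,
    upper) of the time saved among those, and the count/share saving more
    than 30 minutes.
    """
    saved_col, _ = _MODE_COLS[mode]
    df = _routable(results)
    rows = []
    for stratum, sub in _strata_frames(df):
        row: dict = {"stratum": stratum, "n": int(len(sub))}
        if len(sub):
            faster = sub[sub[saved_col] > 0]
            row["heli_faster_n"] = int(len(faster))
            row["heli_faster_pct"] = 100.0 * len(faster) / len(sub)
            if len(faster):
                lo, med, hi = _interval(faster[saved_col].to_numpy(), interval)
                row.update({"saved_median": med, "saved_lower": lo, "saved_upper": hi})
            over30 = sub[sub[saved_col] > 30.0]
            row["saved_gt30_n"] = int(len(over30))
            row["saved_gt30_pct"] = 100.0 * len(over30) / len(sub)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class BreakEvenCurve:
    """Helicopter-fastest fraction binned by the ground transport leg ``g2``.

    ``threshold_min`` is the midpoint of the first bin whose helicopter
    fraction exceeds 0.5 with every later non-empty bin at least 0.5 (plateau
    rule, so sparse noisy bins cannot produce a spurious early crossing);
    ``None`` when no bin crosses.
    """

    mode: Mode
    bin_edges: tuple[float, ...]
    n: tuple[int, ...]
    heli_fastest: tuple[int, ...]
    fraction: tuple[float, ...]
    threshold_min: float | None

    def to_frame(self) -> pd.DataFrame:
        edges = np.asarray(self.bin_edges)
        return pd.DataFrame({
            "bin_left": edges[:-1], "bin_right": edges[1:],
            "bin_mid": (edges[:-1] + edges[1:]) / 2.0,
            "n": self.n, "heli_fastest": self.heli_fastest, "fraction": self.fraction,
        })


def breakeven(
    results: pd.DataFrame, mode: Mode = "simultaneous", bin_width_min: float = 10.0
) -> BreakEvenCurve:
    """Bin routable missions by ``g2`` and find the helicopter break-even bin."""
    if bin_width_min <= 0:
        raise ConfigurationError("bin width must be positive")
    saved_col, _ = _MODE_COLS[mode]
    df = _routable(results)
    g2 = df["g2"].to_numpy(dtype=float)
    heli = (df[saved_col].to_numpy(dtype=float) > 0)
    n_bins = max(1, int(math.floor(g2.max() / bin_width_min)) + 1) if len(g2) else 1
    edges = np.arange(n_bins + 1) * bin_width_min
    idx = np.clip(np.floor(g2 / bin_width_min).astype(int), 0, n_bins - 1) if len(g2) else []
    counts = np.bincount(idx, minlength=n_bins) if len(g2) else np.zeros(n_bins, int)
    heli_counts = (np.bincount(idx, weights=heli, minlength=n_bins).astype(int)
                   if len(g2) else np.zeros(n_bins, int))
    with np.errstate(invalid="ignore"):
        frac = np.where(counts > 0, heli_counts / np.maximum(counts, 1), np.nan)

    threshold = None
    occupied = counts > 0
    for i in range(n_bins):
        if not occupied[i] or not frac[i] > 0.5:
            continue
        later = occupied & (np.arange(n_bins) > i)
        if np.all(frac[later] >= 0.5):
            threshold = float((edges[i] + edges[i + 1]) / 2.0)
            break
    return BreakEvenCurve(
        mode=mode, bin_edges=tuple(float(e) for e in edges),
        n=tuple(int(c) for c in counts), heli_fastest=tuple(int(c) for c in heli_counts),
        fraction=tuple(float(f) for f in frac), threshold_min=threshold,
    )


def render_tables_text(ground: pd.DataFrame, saved_sim: pd.DataFrame,
                       saved_eval: pd.DataFrame) -> str:
    """Human-readable rendering of the two summary tables."""

    def fmt(row, prefix):
        if f"{prefix}_median" not in row or pd.isna(row.get(f"{prefix}_median", math.nan)):
            return "-"
        return (f"{row[f'{prefix}_median']:.1f} "
                f"({row[f'{prefix}_lower']:.1f}-{row[f'{prefix}_upper']:.1f})")

    lines = ["Ground transportation only: total pre-hospital time (min)",
             f"{'stratum':<22}{'n':>8}  {'lysis median (95%)':<22}"
             f"{'thrombectomy median (95%)':<26}{'increase N (%)':<18}{'increase median (95%)'}"]
    for _, r in ground.iterrows():
        inc = (f"{int(r['increase_n'])} ({r['increase_pct']:.1f}%)"
               if r["n"] and not pd.isna(r.get("increase_n", math.nan)) else "-")
        lines.append(f"{r['stratum']:<22}{int(r['n']):>8}  {fmt(r, 'lysis'):<22}"
                     f"{fmt(r, 'thrombectomy'):<26}{inc:<18}{fmt(r, 'increase')}")
    for title, tab in (("Time saved by helicopter, simultaneous dispatch", saved_sim),
                       ("Time saved by helicopter, dispatch after primary evaluation", saved_eval)):
        lines += ["", title,
                  f"{'stratum':<22}{'n':>8}  {'heli faster N (%)':<20}"
                  f"{'saved median (95%)':<22}{'> 30 min saved N (%)'}"]
        for _, r in tab.iterrows():
            if not r["n"] or pd.isna(r.get("heli_faster_n", math.nan)):
                lines.append(f"{r['stratum']:<22}{int(r['n']):>8}  -")
                continue
            hf = f"{int(r['heli_faster_n'])} ({r['heli_faster_pct']:.1f}%)"
            g30 = f"{int(r['saved_gt30_n'])} ({r['saved_gt30_pct']:.1f}%)"
            lines.append(f"{r['stratum']:<22}{int(r['n']):>8}  {hf:<20}"
                         f"{fmt(r, 'saved'):<22}{g30}")
    return "\n".join(lines) + "\n"
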