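"""Pointwise longitudinal analysis of visual-field cohorts.

The core procedure: match each test location's total deviation (TD) between
baseline and a follow-up visit, categorize matched points by their baseline
TD into 5-dB bins, and summarize the change per bin (n, mean, SD, normal
95% CI).  Because test-retest noise is symmetric while binning conditions on
the noisy baseline, per-bin change estimates carry a regression-to-the-mean
component: bins below the cohort point mean drift positive, bins above it
drift negative, even with no true change.

Points are binned on total deviation rather than raw sensitivity: the deep
end of the scale is negative only on the deviation scale, and the bins run
from -35 dB upward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geometry
from .metrics import Cohort, NormativeModel

__all__ = [
    "BinSpec",
    "assign_bin",
    "match_points",
    "change_by_bin",
    "range_subset_stats",
    "effect_size",
    "location_mean_map",
    "md_stratum",
    "map_to_grid",
    "round_half_away",
    "MD_STRATA",
]

DEFAULT_EDGES = (-35.0, -30.0, -25.0, -20.0, -15.0, -10.0, -5.0, 0.0, 5.0, 10.0)

#: MD strata used to categorize eyes by global severity.  Labels follow the
#: clinical convention; intervals are reconciled to a disjoint partition
#: [-2, inf), [-7, -2), (-inf, -7).
MD_STRATA = {
    "all": (-np.inf, np.inf),
    "ge_-2": (-2.0, np.inf),
    "-7_-2": (-7.0, -2.0),
    "le_-7": (-np.inf, -7.0),
}


@dataclass(frozen=True)
class BinSpec:
    """Baseline-deviation bins: half-open intervals [lower, upper).

    ``min_observations`` is the reporting threshold: bins with fewer matched
    points are retained in raw output but flagged unreported (default 10).
    """

    edges: tuple[float, ...] = DEFAULT_EDGES
    min_observations: int = 10

    def __post_init__(self):
        e = self.edges
        if len(e) < 2 or any(a >= b for a, b in zip(e, e[1:])):
            raise ValueError("edges must be strictly ascending with >= 2 values")

    def labels(self) -> list[str]:
        return [f"({_fmt(a)}, {_fmt(b)})" for a, b in zip(self.edges, self.edges[1:])]


def _fmt(v: float) -> str:
    return f"{v:g}"


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (table convention, unlike banker's rounding)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def assign_bin(td_db: float, spec: BinSpec = BinSpec()) -> str | None:
    """The unique bin [lower, upper) containing ``td_db``; None outside the range."""
    e = spec.edges
    if np.isnan(td_db) or td_db < e[0] or td_db >= e[-1]:
        return None
    i = int(np.searchsorted(e, td_db, side="right")) - 1
    return spec.labels()[i]


def match_points(
    cohort: Cohort,
    model: NormativeModel,
    followup_month: int,
    baseline_month: int = 0,
    reliable_only: bool = True,
) -> pd.DataFrame:
    """Pair each location's TD between baseline and a follow-up visit.

    Returns one row per (patient, eye, non-blind-spot location) with a
    non-missing TD at both visits, both eyes pooled: columns patient_id,
    eye, loc_index, baseline_td_db, followup_td_db, change_db, arm,
    on_acetazolamide.  Patients lacking either visit contribute nothing.
    """
    if reliable_only:
        cohort = cohort.reliable()
    td, _ = cohort.deviations(model)
    meta = cohort.meta
    frames = {}
    for month, name in ((baseline_month, "baseline"), (followup_month, "followup")):
        sel = meta["visit_month"].to_numpy() == month
        sub = meta.loc[sel, ["patient_id", "eye", "arm", "on_acetazolamide"]].copy()
        sub["_row"] = np.flatnonzero(sel)
        # one exam per patient/eye/visit; keep the first if duplicated
        sub = sub.drop_duplicates(subset=["patient_id", "eye"], keep="first")
        frames[name] = sub
    merged = frames["baseline"].merge(
        frames["followup"][["patient_id", "eye", "_row"]],
        on=["patient_id", "eye"],
        suffixes=("_b", "_f"),
    )
    if merged.empty:
        return pd.DataFrame(
            columns=["patient_id", "eye", "loc_index", "baseline_td_db",
                     "followup_td_db", "change_db", "arm", "on_acetazolamide"]
        )
    tb = td[merged["_row_b"].to_numpy()]
    tf = td[merged["_row_f"].to_numpy()]
    ok = ~np.isnan(tb) & ~np.isnan(tf)
    n_loc = geometry.N_LOCATIONS
    rep = lambda col: np.repeat(merged[col].to_numpy(), n_loc)[ok.ravel()]
    out = pd.DataFrame(
        {
            "patient_id": rep("patient_id"),
            "eye": rep("eye"),
            "loc_index": np.tile(np.arange(n_loc), len(merged))[ok.ravel()],
            "baseline_td_db": tb[ok],
            "followup_td_db": tf[ok],
            "arm": rep("arm"),
            "on_acetazolamide": rep("on_acetazolamide").astype(bool),
        }
    )
    out["change_db"] = out["followup_td_db"] - out["baseline_td_db"]
    return out[["patient_id", "eye", "loc_index", "baseline_td_db",
                "followup_td_db", "change_db", "arm", "on_acetazolamide"]]


def change_by_bin(
    points: pd.DataFrame,
    spec: BinSpec = BinSpec(),
    ci_method: str = "normal",
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-bin longitudinal change summary.

    Columns: bin, bin_lo, bin_hi, n_points, mean_baseline_db, mean_change_db,
    sd_change_db (n-1 denominator), ci_low, ci_high, reported.  The default
    CI is the normal approximation mean +/- 1.96 SD/sqrt(n), treating points
    as independent; ``ci_method='cluster_bootstrap'`` instead resamples
    patients with replacement (percentile interval), acknowledging
    within-patient correlation.  Bins with fewer than ``min_observations``
    points keep their row but have ``reported=False``.
    """
    e = np.asarray(spec.edges)
    labels = spec.labels()
    base = points["baseline_td_db"].to_numpy()
    chg = points["change_db"].to_numpy()
    which = np.searchsorted(e, base, side="right") - 1
    in_range = (base >= e[0]) & (base < e[-1])
    rows = []
    for i, lab in enumerate(labels):
        sel = in_range & (which == i)
        n = int(sel.sum())
        if n == 0:
            rows.append((lab, e[i], e[i + 1], 0, np.nan, np.nan, np.nan, np.nan, np.nan, False))
            continue
        c = chg[sel]
        mean = float(c.mean())
        sd = float(c.std(ddof=1)) if n > 1 else np.nan
        if ci_method == "normal":
            half = 1.96 * sd / math.sqrt(n) if n > 1 else np.nan
            lo, hi = mean - half, mean + half
        elif ci_method == "cluster_bootstrap":
            lo, hi = _cluster_bootstrap_ci(points.loc[sel], n_boot, rng)
        else:
            raise ValueError(f"unknown ci_method {ci_method!r}")
        rows.append(
            (lab, e[i], e[i + 1], n, float(base[sel].mean()), mean, sd, lo, hi,
             n >= spec.min_observations)
        )
    return pd.DataFrame(
        rows,
        columns=["bin", "bin_lo", "bin_hi", "n_points", "mean_baseline_db",
                 "mean_change_db", "sd_change_db", "ci_low", "ci_high", "reported"],
    )


def _cluster_bootstrap_ci(points: pd.DataFrame, n_boot: int, rng) -> tuple[float, float]:
    rng = np.random.default_rng(rng)
    patients = points["patient_id"].unique()
    by_pat = {p: g["change_db"].to_numpy() for p, g in points.groupby("patient_id")}
    means = np.empty(n_boot)
    for b in range(n_boot):
        pick = rng.choice(patients, size=len(patients), replace=True)
        vals = np.concatenate([by_pat[p] for p in pick])
        means[b] = vals.mean()
    lo, hi = np.percentile(means, [2.5, 97.5])
    return float(lo), float(hi)


def range_subset_stats(
    points: pd.DataFrame,
    lo: float = -25.0,
    hi: float = -10.0,
    group_by: str = "whole",
) -> pd.DataFrame:
    """Change summary restricted to baseline TD in [lo, hi).

    ``group_by``: 'whole' (one row), 'arm', or 'arm_acetazolamide' (trial
    arm crossed with acetazolamide use within the community-weight arm).
    Columns: group, n_points, mean_change_db, sd_change_db, degenerate
    (True when the SD is undefined, i.e. fewer than 2 points).
    """
    if not lo < hi:
        raise ValueError("lo must be < hi")
    sub = points[(points["baseline_td_db"] >= lo) & (points["baseline_td_db"] < hi)]

    def summarize(label, g):
        n = len(g)
        mean = float(g["change_db"].mean()) if n else np.nan
        sd = float(g["change_db"].std(ddof=1)) if n > 1 else np.nan
        return {"group": label, "n_points": n, "mean_change_db": mean,
                "sd_change_db": sd, "degenerate": n < 2}

    if group_by == "whole":
        rows = [summarize("whole", sub)]
    elif group_by == "arm":
        rows = [summarize(arm, sub[sub["arm"] == arm]) for arm in ("bariatric", "cwi")]
    elif group_by == "arm_acetazolamide":
        cwi = sub[sub["arm"] == "cwi"]
        rows = [
            summarize("whole", sub),
            summarize("bariatric", sub[sub["arm"] == "bariatric"]),
            summarize("cwi", cwi),
            summarize("cwi_acetazolamide", cwi[cwi["on_acetazolamide"]]),
            summarize("cwi_no_acetazolamide", cwi[~cwi["on_acetazolamide"]]),
        ]
    else:
        raise ValueError(f"unknown group_by {group_by!r}")
    return pd.DataFrame(rows)


def effect_size(mean_change_db: float, sd_change_db: float) -> float:
    """Standardized mean change: mean / SD of the changes.

    Full precision; reports round to 2 decimals half-away-from-zero.
    Raises on non-positive SD (degenerate dispersion).
    """
    if not sd_change_db > 0:
        raise ValueError("degenerate dispersion: sd_change_db must be > 0")
    return mean_change_db / sd_change_db


def md_stratum(md_db: float) -> str:
    """Severity stratum of an MD: 'ge_-2', '-7_-2', or 'le_-7' (disjoint)."""
    if md_db >= -2.0:
        return "ge_-2"
    if md_db >= -7.0:
        return "-7_-2"
    return "le_-7"


def location_mean_map(
    cohort: Cohort,
    model: NormativeModel,
    stratum: str = "all",
    visit_month: int = 0,
    reliable_only: bool = True,
) -> np.ndarray:
    """Per-location mean baseline TD over eyes in an MD stratum.

    Returns a (54,) array (NaN at the blind spot), averaging the TD field of
    every contributing eye at ``visit_month`` whose own MD falls in the
    stratum.  An empty stratum yields an all-NaN map.
    """
    if stratum not in MD_STRATA:
        raise ValueError(f"unknown stratum {stratum!r}; options {list(MD_STRATA)}")
    if reliable_only:
        cohort = cohort.reliable()
    td, md = cohort.deviations(model)
    lo, hi = MD_STRATA[stratum]
    sel = (cohort.meta["visit_month"].to_numpy() == visit_month) & (md >= lo)
    if stratum == "-7_-2":
        sel &= md < hi
    elif stratum == "ge_-2":
        pass
    elif stratum == "le_-7":
        sel = (cohort.meta["visit_month"].to_numpy() == visit_month) & (md < -7.0)
    out = np.full(geometry.N_LOCATIONS, np.nan)
    if not sel.any():
        return out
    ok = geometry.analyzable_mask()
    sub = td[sel][:, ok]
    counts = (~np.isnan(sub)).sum(axis=0)
    sums = np.nansum(sub, axis=0)
    out[ok] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return out


def map_to_grid(values: np.ndarray) -> pd.DataFrame:
    """Lay a (54,) per-location vector out as a y-by-x grid for heatmaps.

    Rows are y (superior first), columns x (nasal to temporal); cells not in
    the pattern are NaN.
    """
    xy = geometry.coords()
    xs = sorted(set(xy[:, 0]))
    ys = sorted(set(xy[:, 1]), reverse=True)
    grid = pd.DataFrame(np.nan, index=ys, columns=xs)
    for (x, y), v in zip(xy, values):
        grid.loc[y, x] = v
    grid.index.name = "y_deg"
    grid.columns.name = "x_deg"
    return grid
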