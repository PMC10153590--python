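"""End-to-end report assembly.

``run_pipeline`` takes a cohort (from CSV or a named synthetic preset) and
writes the full set of tidy outputs: per-visit bin-change tables, the
range-subset and effect-size tables, the eligibility-restricted point-count
table, the feasibility and responder tables, and per-stratum location maps,
plus the resolved configuration and a run log recording attrition.  All
statistics are computed at full precision; rounding happens only at
serialization.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import feasibility as fz
from . import pointwise as pw
from . import simulate
from .metrics import Cohort, NormativeModel, read_exams_csv

__all__ = ["RunConfig", "run_pipeline", "load_cohort"]

log = logging.getLogger("vfpoint")

PRESET_NAMES = ("null", "mild_medical", "iihwt_like")

#: coarse deviation ranges for the eligibility-restricted point-count table
RESTRICTED_RANGES = ((-10.0, 0.0), (-25.0, -10.0), (-35.0, -25.0))


@dataclass(frozen=True)
class RunConfig:
    """Resolved pipeline configuration; echoed verbatim into the output dir."""

    input: str = "iihwt_like"          # CSV path or preset name
    outdir: str = "vfpoint_out"
    bin_edges: tuple[float, ...] = pw.DEFAULT_EDGES
    min_observations: int = 10
    md_window: tuple[float, float] = (-7.0, -2.0)
    qualifying_db: float = -10.0
    responder_db: float = 7.0
    visit_months: tuple[int, ...] | None = None   # follow-ups; inferred if None
    unit: str = "worse_eye"
    round_digits: int = 2
    seed: int = 0


def load_cohort(config: RunConfig, model: NormativeModel) -> Cohort:
    """Resolve ``config.input`` to a cohort: preset name or long-format CSV."""
    if config.input in PRESET_NAMES:
        cc = dataclasses.replace(simulate.preset(config.input), seed=config.seed)
        cohort, _ = simulate.generate(cc, model)
        return cohort
    path = Path(config.input)
    if not path.exists():
        raise FileNotFoundError(f"input {config.input!r} is neither a preset nor a readable file")
    return read_exams_csv(path)


def _round_for_report(df: pd.DataFrame, digits: int) -> pd.DataFrame:
    out = df.copy()
    for c in out.columns:
        if pd.api.types.is_float_dtype(out[c]):
            out[c] = out[c].map(
                lambda v: v if pd.isna(v) else pw.round_half_away(float(v), digits)
            )
    return out


def _write(df: pd.DataFrame, path: Path, digits: int) -> None:
    _round_for_report(df, digits).to_csv(path, index=False)


def run_pipeline(
    config: RunConfig,
    model: NormativeModel = NormativeModel(),
    cohort: Cohort | None = None,
) -> dict[str, Path]:
    """Run the full analysis and write every report; returns output paths."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    outputs: dict[str, Path] = {}
    try:
        if cohort is None:
            cohort = load_cohort(config, model)
        n_total = len(cohort)
        reliable = cohort.reliable()
        log.info("exams total=%d reliable=%d excluded_unreliable=%d",
                 n_total, len(reliable), n_total - len(reliable))
        baseline_n = (reliable.meta["visit_month"] == 0).sum()
        if baseline_n == 0:
            raise ValueError("no reliable baseline exams; nothing to analyze")
        log.info("reliable baseline exams=%d patients=%d",
                 baseline_n, reliable.meta["patient_id"].nunique())

        months = config.visit_months
        if months is None:
            months = tuple(
                sorted(m for m in reliable.meta["visit_month"].unique() if m != 0)
            )
        spec = pw.BinSpec(edges=config.bin_edges, min_observations=config.min_observations)

        # (a) per-visit bin-change tables
        points_by_month: dict[int, pd.DataFrame] = {}
        for t in months:
            points = pw.match_points(reliable, model, t, reliable_only=False)
            points_by_month[t] = points
            log.info("visit %d: matched points=%d", t, len(points))
            table = pw.change_by_bin(points, spec)
            p_raw = outdir / f"table2_binchange_{t}_raw.csv"
            _write(table, p_raw, config.round_digits)
            p = outdir / f"table2_binchange_{t}.csv"
            _write(table[table["reported"]].drop(columns="reported"), p, config.round_digits)
            outputs[f"binchange_{t}"] = p
            outputs[f"binchange_{t}_raw"] = p_raw

        # (b) range-subset table by arm/acetazolamide, with effect sizes
        rows3, rows5 = [], []
        for t in months:
            sub = pw.range_subset_stats(
                points_by_month[t], -25.0, -10.0, group_by="arm_acetazolamide"
            )
            sub.insert(0, "visit_month", t)
            rows3.append(sub)
            es = sub.copy()
            es["effect_size"] = [
                np.nan if (row.degenerate or not row.sd_change_db > 0)
                else pw.effect_size(row.mean_change_db, row.sd_change_db)
                for row in sub.itertuples()
            ]
            rows5.append(es)
        p3 = outdir / "table3_rangesubset.csv"
        _write(pd.concat(rows3, ignore_index=True), p3, config.round_digits)
        outputs["rangesubset"] = p3
        p5 = outdir / "table5_effectsizes.csv"
        _write(pd.concat(rows5, ignore_index=True), p5, config.round_digits)
        outputs["effectsizes"] = p5

        # (c) eligibility-restricted point counts per coarse range
        window = fz.EligibilityWindow(*config.md_window, unit=config.unit)
        md_tab = fz.baseline_md_table(reliable, model, reliable_only=False)
        elig_ids = {
            pid
            for pid, g in md_tab.groupby("patient_id")
            if fz.eligible(dict(zip(g["eye"], g["md_db"])), window)
        }
        log.info("eligible patients (MD window %s)=%d of %d",
                 config.md_window, len(elig_ids), md_tab["patient_id"].nunique())
        rows4 = []
        for t in months:
            pts = points_by_month[t]
            pts = pts[pts["patient_id"].isin(elig_ids)]
            for lo, hi in RESTRICTED_RANGES:
                r = pw.range_subset_stats(pts, lo, hi, group_by="whole").iloc[0]
                rows4.append(
                    {"range_db": f"[{lo:g}, {hi:g})", "visit_month": t,
                     "n_points": r["n_points"], "mean_change_db": r["mean_change_db"],
                     "sd_change_db": r["sd_change_db"]}
                )
        p4 = outdir / "table4_restricted_counts.csv"
        _write(pd.DataFrame(rows4), p4, config.round_digits)
        outputs["restricted_counts"] = p4

        # (d) feasibility table
        p6 = outdir / "table6_feasibility.csv"
        _write(fz.feasibility_table(reliable, model, config.qualifying_db), p6,
               config.round_digits)
        outputs["feasibility"] = p6

        # (e) responder table
        rows7 = []
        for t in months:
            tab = fz.responder_table(points_by_month[t], config.responder_db)
            tab.insert(0, "visit_month", t)
            tab["n_participants"] = tab.attrs["n_participants"]
            rows7.append(tab)
        p7 = outdir / "table7_responders.csv"
        _write(pd.concat(rows7, ignore_index=True), p7, config.round_digits)
        outputs["responders"] = p7

        # (f) location maps per MD stratum
        for stratum in pw.MD_STRATA:
            m = pw.location_mean_map(reliable, model, stratum, reliable_only=False)
            grid = pw.map_to_grid(m)
            pmap = outdir / f"fig1_map_{stratum}.csv"
            _round_for_report(grid.reset_index(), config.round_digits).to_csv(
                pmap, index=False
            )
            outputs[f"map_{stratum}"] = pmap

        resolved = outdir / "resolved_config.json"
        resolved.write_text(json.dumps(dataclasses.asdict(config), indent=2, default=str))
        outputs["config"] = resolved
        log.info("pipeline complete: %d outputs in %s", len(outputs), outdir)
        return outputs
    finally:
        log.removeHandler(handler)
        handler.close()
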