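"""Participant-level feasibility analytics.

A medically managed population is simulated by restricting to patients whose
baseline worse-eye MD lies in a window (default [-7, -2] dB, the usual
inclusion range for a medical treatment trial).  For trial planning the
questions are then: how many patients carry at least k deep test points
(baseline TD at or beyond -10 dB, either eye), and how many points per
patient actually improve by the 7-dB clinically meaningful margin at
follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import geometry
from .metrics import Cohort, NormativeModel
from .pointwise import md_stratum, round_half_away

__all__ = [
    "EligibilityWindow",
    "baseline_md_table",
    "eligible",
    "qualifying_points",
    "qualifying_points_table",
    "feasibility_table",
    "responder_counts",
    "responder_table",
    "RESPONDER_CATEGORIES",
]

RESPONDER_CATEGORIES = ("0", "1", "2", "3", "4", "5", ">5")


@dataclass(frozen=True)
class EligibilityWindow:
    """Baseline-MD inclusion window, closed on both ends.

    ``unit='worse_eye'`` evaluates the patient's worse (minimum) MD;
    ``'per_eye'`` evaluates each eye on its own.
    """

    md_low_db: float = -7.0
    md_high_db: float = -2.0
    unit: str = "worse_eye"

    def __post_init__(self):
        if not self.md_low_db < self.md_high_db:
            raise ValueError("md_low_db must be < md_high_db")
        if self.unit not in ("worse_eye", "per_eye"):
            raise ValueError(f"unknown unit {self.unit!r}")


def baseline_md_table(
    cohort: Cohort,
    model: NormativeModel,
    baseline_month: int = 0,
    reliable_only: bool = True,
) -> pd.DataFrame:
    """One row per reliable baseline exam: patient_id, eye, md_db."""
    if reliable_only:
        cohort = cohort.reliable()
    _, md = cohort.deviations(model)
    meta = cohort.meta
    sel = meta["visit_month"].to_numpy() == baseline_month
    out = meta.loc[sel, ["patient_id", "eye"]].copy()
    out["md_db"] = md[sel]
    return out.drop_duplicates(subset=["patient_id", "eye"], keep="first").reset_index(drop=True)


def eligible(md_by_eye: dict | pd.Series, window: EligibilityWindow = EligibilityWindow()):
    """Eligibility of one patient given baseline MD per eye.

    ``worse_eye``: True iff min(MD) falls inside [md_low, md_high] (inclusive).
    ``per_eye``: returns a dict of per-eye flags.  No reliable baseline
    (empty input) is ineligible.
    """
    mds = dict(md_by_eye)
    if not mds:
        return False if window.unit == "worse_eye" else {}
    if window.unit == "worse_eye":
        worst = min(mds.values())
        return bool(window.md_low_db <= worst <= window.md_high_db)
    return {e: bool(window.md_low_db <= m <= window.md_high_db) for e, m in mds.items()}


def qualifying_points(
    td_fields,
    threshold_db: float = -10.0,
    strict: bool = False,
) -> int:
    """Number of deep points across a patient's eyes at baseline.

    Counts non-blind-spot locations with TD <= threshold (or < with
    ``strict=True``) summed over the 1-2 supplied TD fields.
    """
    total = 0
    mask = geometry.analyzable_mask()
    for td in td_fields:
        td = np.asarray(td, dtype=float)
        vals = td[mask & ~np.isnan(td)]
        total += int((vals < threshold_db).sum() if strict else (vals <= threshold_db).sum())
    return total


def qualifying_points_table(
    cohort: Cohort,
    model: NormativeModel,
    threshold_db: float = -10.0,
    strict: bool = False,
    baseline_month: int = 0,
) -> pd.DataFrame:
    """Per-patient qualifying-point counts and worse-eye baseline MD.

    Columns: patient_id, n_qualifying, worse_eye_md_db, stratum.  Only
    reliable baseline exams contribute.
    """
    rel = cohort.reliable()
    td, md = rel.deviations(model)
    meta = rel.meta
    sel = meta["visit_month"].to_numpy() == baseline_month
    rows = []
    for pid, g in meta.loc[sel].groupby("patient_id", sort=True):
        g = g.drop_duplicates(subset="eye", keep="first")
        idx = g.index.to_numpy()
        n_q = qualifying_points(td[idx], threshold_db, strict)
        worse = float(np.min(md[idx]))
        rows.append({"patient_id": pid, "n_qualifying": n_q,
                     "worse_eye_md_db": worse, "stratum": md_stratum(worse)})
    return pd.DataFrame(rows, columns=["patient_id", "n_qualifying",
                                       "worse_eye_md_db", "stratum"])


def feasibility_table(
    cohort: Cohort,
    model: NormativeModel,
    threshold_db: float = -10.0,
    k_max: int = 5,
) -> pd.DataFrame:
    """Participants with >= k deep baseline points, per MD stratum.

    One row per population (whole cohort plus the three worse-eye MD
    strata): n, count/proportion with >= k qualifying points for k = 1..k_max
    (proportions rounded to 2 decimals), and the median (IQR, linear
    interpolation) of qualifying counts among participants with >= 1.
    """
    per = qualifying_points_table(cohort, model, threshold_db)
    populations = [("whole", per)] + [
        (s, per[per["stratum"] == s]) for s in ("ge_-2", "-7_-2", "le_-7")
    ]
    rows = []
    for label, g in populations:
        n = len(g)
        row = {"population": label, "n_participants": n}
        counts = g["n_qualifying"].to_numpy()
        for k in range(1, k_max + 1):
            c = int((counts >= k).sum())
            row[f"count_ge_{k}"] = c
            row[f"prop_ge_{k}"] = round_half_away(c / n, 2) if n else np.nan
        has = counts[counts >= 1]
        if has.size:
            q1, med, q3 = np.percentile(has, [25, 50, 75])  # linear interpolation
            row.update(median_points=float(med), iqr_low=float(q1), iqr_high=float(q3))
        else:
            row.update(median_points=np.nan, iqr_low=np.nan, iqr_high=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def responder_counts(points: pd.DataFrame, delta_db: float = 7.0) -> pd.Series:
    """Per-patient number of points improved by >= delta from baseline.

    ``points`` is a matched-point table (both eyes pooled); returns a Series
    indexed by patient_id.
    """
    improved = points["change_db"] >= delta_db
    return improved.groupby(points["patient_id"]).sum().astype(int)


def responder_table(points: pd.DataFrame, delta_db: float = 7.0) -> pd.DataFrame:
    """Participants cross-tabulated by improved-point count {0..5, >5}.

    Percentages are of the visit's analyzable N (patients with at least one
    matched point), rounded half-away-from-zero to whole percent.
    """
    counts = responder_counts(points, delta_db)
    n_total = len(counts)
    rows = []
    for cat in RESPONDER_CATEGORIES:
        if cat == ">5":
            c = int((counts > 5).sum())
        else:
            c = int((counts == int(cat)).sum())
        pct = round_half_away(100.0 * c / n_total, 0) if n_total else np.nan
        rows.append({"category": cat, "n": c, "percent": pct})
    out = pd.DataFrame(rows)
    out.attrs["n_participants"] = n_total
    return out
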