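"""Per-exam derived quantities and the exam container.

Total deviation (TD) is a location's measured sensitivity minus the
age-corrected normal sensitivity at that location.  Mean deviation (MD) is
the variance-inverse-weighted average of TD over the 52 non-blind-spot
locations; weighting by the inverse of normal-population variance gives more
influence to central locations, which are the least variable in healthy eyes.

The instrument vendor's normative surface and weight table are proprietary,
so :class:`NormativeModel` is pluggable.  The shipped default is a simple
parametric surface — sensitivity falling linearly with eccentricity and age,
variance growing linearly with eccentricity — which reproduces the
qualitative structure (central weighting, hill of vision) without claiming
the vendor's numbers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Literal

import numpy as np
import pandas as pd

from . import geometry
from .geometry import Eye, N_LOCATIONS

__all__ = [
    "EmptyExamError",
    "NormativeModel",
    "VFExam",
    "DeviationField",
    "Cohort",
    "total_deviation",
    "mean_deviation",
    "is_reliable",
    "read_exams_csv",
    "write_exams_csv",
    "exam_to_json",
    "exam_from_json",
    "RELIABILITY_LIMITS",
]

#: exam acceptance limits: false positives < 15%, fixation losses and false
#: negatives < 30% (strict inequalities; a boundary value fails)
RELIABILITY_LIMITS = {"fp_rate": 0.15, "fl_rate": 0.30, "fn_rate": 0.30}

SENS_MIN_DB = 0.0
SENS_MAX_DB = 40.0


class EmptyExamError(ValueError):
    """Raised when an operation needs at least one non-missing sensitivity."""


@dataclass(frozen=True)
class NormativeModel:
    """Age-corrected normal sensitivity surface and MD weights.

    ``normal_sensitivity = c0 - c1 * eccentricity - c2 * (age - 20)`` and
    ``weight = 1 / (s0 + s1 * eccentricity)**2`` (inverse normal-population
    variance).  Defaults give ~34 dB centrally at age 20, a hill of vision
    sloping 0.25 dB/deg, ~0.7 dB loss per decade of age, and roughly
    twofold down-weighting of the outermost ring relative to the centre.
    """

    c0_db: float = 34.0
    c1_db_per_deg: float = 0.25
    c2_db_per_year: float = 0.07
    s0_db: float = 1.5
    s1_db_per_deg: float = 0.05

    def normal_sensitivity(self, eccentricity_deg, age_years):
        """Expected normal sensitivity (dB); vectorized over eccentricity."""
        ecc = np.asarray(eccentricity_deg, dtype=float)
        return self.c0_db - self.c1_db_per_deg * ecc - self.c2_db_per_year * (age_years - 20.0)

    def weight(self, eccentricity_deg):
        """MD weight = inverse normal-population variance; strictly positive."""
        ecc = np.asarray(eccentricity_deg, dtype=float)
        return 1.0 / (self.s0_db + self.s1_db_per_deg * ecc) ** 2

    def normal_surface(self, age_years: float) -> np.ndarray:
        """(54,) normal sensitivities over the pattern for one age."""
        return self.normal_sensitivity(geometry.eccentricities(), age_years)

    def pattern_weights(self) -> np.ndarray:
        """(54,) weights over the pattern (blind-spot entries included but unused)."""
        return self.weight(geometry.eccentricities())


@dataclass
class VFExam:
    """One eye's visual-field exam at one visit.

    ``sensitivity_db`` is aligned to :func:`vfpoint.geometry.pattern_24_2`
    ordering (54 values, canonical frame); missing locations are NaN.
    """

    patient_id: str
    eye: Eye
    visit_month: int
    age_years: float
    sensitivity_db: np.ndarray
    fp_rate: float
    fn_rate: float
    fl_rate: float
    arm: str = "cwi"
    on_acetazolamide: bool = False

    def __post_init__(self):
        self.eye = Eye(self.eye)
        self.sensitivity_db = np.asarray(self.sensitivity_db, dtype=float)
        if self.sensitivity_db.shape != (N_LOCATIONS,):
            raise ValueError(
                f"sensitivity_db must have {N_LOCATIONS} values, got {self.sensitivity_db.shape}"
            )
        vals = self.sensitivity_db[~np.isnan(self.sensitivity_db)]
        if vals.size and (vals.min() < SENS_MIN_DB or vals.max() > SENS_MAX_DB):
            raise ValueError("sensitivities must lie in [0, 40] dB or be NaN")
        for name in ("fp_rate", "fn_rate", "fl_rate"):
            r = getattr(self, name)
            if r is not None and not np.isnan(r) and not 0.0 <= r <= 1.0:
                raise ValueError(f"{name}={r} outside [0, 1]")


@dataclass(frozen=True)
class DeviationField:
    """Per-location total deviations and the exam's mean deviation.

    ``td_db`` has 54 entries aligned to the pattern; blind-spot locations and
    missing measurements are NaN.  ``md_db`` is the weighted mean of the
    non-missing TDs.
    """

    td_db: np.ndarray
    md_db: float


def is_reliable(
    exam: VFExam,
    missing_policy: Literal["unreliable", "reliable"] = "unreliable",
) -> bool:
    """Exam reliability filter: fp < 15%, fixation losses < 30%, fn < 30%.

    Strict inequalities, so an exam exactly at a limit fails.  A missing
    index is treated per ``missing_policy`` (default: exam is unreliable).
    """
    for name, limit in RELIABILITY_LIMITS.items():
        r = getattr(exam, name)
        if r is None or np.isnan(r):
            if missing_policy == "unreliable":
                return False
            continue
        if not r < limit:
            return False
    return True


def total_deviation(exam: VFExam, model: NormativeModel) -> DeviationField:
    """TD = measured - age-normal sensitivity per non-blind-spot location.

    Blind-spot locations carry no deviation (NaN); missing sensitivities
    propagate as missing deviations.  Raises :class:`EmptyExamError` if no
    analyzable location has a measurement.
    """
    td = exam.sensitivity_db - model.normal_surface(exam.age_years)
    td = np.where(geometry.analyzable_mask(), td, np.nan)
    if np.all(np.isnan(td)):
        raise EmptyExamError(f"exam {exam.patient_id}/{exam.eye.value} has no analyzable values")
    return DeviationField(td_db=td, md_db=mean_deviation(td, model))


def mean_deviation(td_db: np.ndarray | DeviationField, model: NormativeModel) -> float:
    """Weighted mean of non-missing TDs: MD = sum(w_i td_i) / sum(w_i)."""
    td = td_db.td_db if isinstance(td_db, DeviationField) else np.asarray(td_db, dtype=float)
    w = model.pattern_weights()
    ok = ~np.isnan(td) & geometry.analyzable_mask()
    if not ok.any():
        raise EmptyExamError("no non-missing total deviations")
    return float(np.sum(w[ok] * td[ok]) / np.sum(w[ok]))


# ---------------------------------------------------------------------------
# Cohort container


class Cohort:
    """A collection of exams: per-exam metadata plus a sensitivity matrix.

    ``meta`` is one row per exam (patient_id, eye, visit_month, age_years,
    fp/fn/fl rates, arm, on_acetazolamide) and ``sens`` is the aligned
    (n_exams, 54) matrix in canonical pattern order.
    """

    META_COLUMNS = [
        "patient_id", "eye", "visit_month", "age_years",
        "fp_rate", "fn_rate", "fl_rate", "arm", "on_acetazolamide",
    ]

    def __init__(self, meta: pd.DataFrame, sens: np.ndarray):
        meta = meta.reset_index(drop=True)
        sens = np.asarray(sens, dtype=float)
        if sens.shape != (len(meta), N_LOCATIONS):
            raise ValueError(f"sens shape {sens.shape} does not match {len(meta)} exams")
        missing = [c for c in self.META_COLUMNS if c not in meta.columns]
        if missing:
            raise ValueError(f"meta missing columns: {missing}")
        self.meta = meta
        self.sens = sens

    def __len__(self) -> int:
        return len(self.meta)

    def exams(self) -> Iterator[VFExam]:
        for i, row in self.meta.iterrows():
            yield VFExam(
                patient_id=row["patient_id"],
                eye=Eye(row["eye"]),
                visit_month=int(row["visit_month"]),
                age_years=float(row["age_years"]),
                sensitivity_db=self.sens[i],
                fp_rate=float(row["fp_rate"]),
                fn_rate=float(row["fn_rate"]),
                fl_rate=float(row["fl_rate"]),
                arm=row["arm"],
                on_acetazolamide=bool(row["on_acetazolamide"]),
            )

    @classmethod
    def from_exams(cls, exams: Iterable[VFExam]) -> "Cohort":
        exams = list(exams)
        meta = pd.DataFrame(
            {
                "patient_id": [e.patient_id for e in exams],
                "eye": [e.eye.value for e in exams],
                "visit_month": [e.visit_month for e in exams],
                "age_years": [e.age_years for e in exams],
                "fp_rate": [e.fp_rate for e in exams],
                "fn_rate": [e.fn_rate for e in exams],
                "fl_rate": [e.fl_rate for e in exams],
                "arm": [e.arm for e in exams],
                "on_acetazolamide": [e.on_acetazolamide for e in exams],
            }
        )
        sens = np.vstack([e.sensitivity_db for e in exams]) if exams else np.empty((0, N_LOCATIONS))
        return cls(meta, sens)

    def reliability_flags(self) -> np.ndarray:
        """Vectorized per-exam reliability (strict thresholds, NaN fails)."""
        m = self.meta
        ok = np.ones(len(m), dtype=bool)
        for name, limit in RELIABILITY_LIMITS.items():
            r = m[name].to_numpy(dtype=float)
            ok &= ~np.isnan(r) & (r < limit)
        return ok

    def reliable(self) -> "Cohort":
        """Subset of exams passing the reliability filter."""
        keep = self.reliability_flags()
        return Cohort(self.meta.loc[keep], self.sens[keep])

    def select(self, mask) -> "Cohort":
        mask = np.asarray(mask)
        return Cohort(self.meta.loc[mask], self.sens[mask])

    def deviations(self, model: NormativeModel) -> tuple[np.ndarray, np.ndarray]:
        """(td, md): TD matrix (n, 54; NaN at blind spot/missing) and MD vector."""
        ages = self.meta["age_years"].to_numpy(dtype=float)
        ecc = geometry.eccentricities()
        normal = (
            model.c0_db
            - model.c1_db_per_deg * ecc[None, :]
            - model.c2_db_per_year * (ages[:, None] - 20.0)
        )
        td = self.sens - normal
        td[:, ~geometry.analyzable_mask()] = np.nan
        w = model.pattern_weights()
        ok = ~np.isnan(td)
        wsum = np.where(ok, w[None, :], 0.0).sum(axis=1)
        with np.errstate(invalid="ignore"):
            md = np.where(ok, w[None, :] * td, 0.0).sum(axis=1) / np.where(wsum > 0, wsum, np.nan)
        return td, md

    # -- I/O ---------------------------------------------------------------

    def to_long_frame(self) -> pd.DataFrame:
        """Long format, chart-frame coordinates (left-eye x mirrored)."""
        pat = geometry.pattern_frame()
        n = len(self)
        rows = pd.DataFrame(
            np.repeat(self.meta[self.META_COLUMNS].to_numpy(), N_LOCATIONS, axis=0),
            columns=self.META_COLUMNS,
        )
        rows["x_deg"] = np.tile(pat["x_deg"].to_numpy(), n)
        rows["y_deg"] = np.tile(pat["y_deg"].to_numpy(), n)
        left = rows["eye"].to_numpy() == Eye.LEFT.value
        rows.loc[left, "x_deg"] = -rows.loc[left, "x_deg"]
        rows["sensitivity_db"] = self.sens.ravel()
        cols = [
            "patient_id", "eye", "visit_month", "age_years", "x_deg", "y_deg",
            "sensitivity_db", "fp_rate", "fn_rate", "fl_rate", "arm", "on_acetazolamide",
        ]
        return rows[cols]

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame) -> "Cohort":
        df = df.copy()
        x = df["x_deg"].to_numpy(dtype=float)
        left = df["eye"].to_numpy() == Eye.LEFT.value
        x = np.where(left, -x, x)  # chart -> canonical
        y = df["y_deg"].to_numpy(dtype=float)
        idx = np.array([geometry.location_index(xi, yi) for xi, yi in zip(x, y)])
        key_cols = ["patient_id", "eye", "visit_month"]
        meta_cols = cls.META_COLUMNS
        groups = df.groupby(key_cols, sort=True)
        metas, senses = [], []
        for _, g in groups:
            row = g.iloc[0]
            metas.append({c: row[c] for c in meta_cols})
            s = np.full(N_LOCATIONS, np.nan)
            gi = idx[g.index.to_numpy()]
            s[gi] = g["sensitivity_db"].to_numpy(dtype=float)
            senses.append(s)
        meta = pd.DataFrame(metas)
        meta["visit_month"] = meta["visit_month"].astype(int)
        meta["on_acetazolamide"] = meta["on_acetazolamide"].astype(bool)
        return cls(meta, np.vstack(senses))

    def to_csv(self, path) -> None:
        self.to_long_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Cohort":
        return cls.from_long_frame(pd.read_csv(path))


def read_exams_csv(path) -> Cohort:
    """Read a long-format exam CSV (chart-frame coordinates) into a Cohort."""
    return Cohort.from_csv(path)


def write_exams_csv(cohort: Cohort, path) -> None:
    """Write a Cohort to long-format CSV (chart-frame coordinates)."""
    cohort.to_csv(path)


def exam_to_json(exam: VFExam) -> str:
    """Serialize one exam to JSON with an explicit pattern ordering."""
    pat = geometry.pattern_frame()
    chart = [geometry.to_chart_frame((x, y), exam.eye)
             for x, y in zip(pat["x_deg"], pat["y_deg"])]
    return json.dumps(
        {
            "patient_id": exam.patient_id,
            "eye": exam.eye.value,
            "visit_month": exam.visit_month,
            "age_years": exam.age_years,
            "fp_rate": exam.fp_rate,
            "fn_rate": exam.fn_rate,
            "fl_rate": exam.fl_rate,
            "arm": exam.arm,
            "on_acetazolamide": exam.on_acetazolamide,
            "locations": [
                {"x_deg": cx, "y_deg": cy, "sensitivity_db": None if np.isnan(s) else s}
                for (cx, cy), s in zip(chart, exam.sensitivity_db)
            ],
        }
    )


def exam_from_json(text: str) -> VFExam:
    """Inverse of :func:`exam_to_json`."""
    d = json.loads(text)
    eye = Eye(d["eye"])
    sens = np.full(N_LOCATIONS, np.nan)
    for loc in d["locations"]:
        cx, cy = geometry.from_chart_frame((loc["x_deg"], loc["y_deg"]), eye)
        s = loc["sensitivity_db"]
        sens[geometry.location_index(cx, cy)] = np.nan if s is None else s
    return VFExam(
        patient_id=d["patient_id"],
        eye=eye,
        visit_month=d["visit_month"],
        age_years=d["age_years"],
        sensitivity_db=sens,
        fp_rate=d["fp_rate"],
        fn_rate=d["fn_rate"],
        fl_rate=d["fl_rate"],
        arm=d["arm"],
        on_acetazolamide=d["on_acetazolamide"],
    )
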