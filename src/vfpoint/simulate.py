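"""Synthetic longitudinal visual-field cohorts.

Generates two-eye, multi-visit 24-2 cohorts with the statistical structure
the pointwise analysis assumes:

* **Defect topography** — loss concentrated peripherally and around the
  blind spot.  Each patient draws a log-normal severity ``S_p`` (dB); each
  location's true defect is ``D = -S_p * m_e * (w_ecc * ecc/27.2 +
  w_bs * adj + w_loc * U)`` where ``m_e`` is a per-eye multiplier (0.8-1.2,
  the two eyes share the patient severity because the disease is bilateral),
  ``adj`` flags the six locations ringing the blind spot, and ``U`` is
  uniform local texture.  Defects are loss-only; supranormal values arise
  only from measurement noise.
* **Depth-dependent test-retest noise** — measurement error is
  ``Normal(0, sigma0 + sigma1 * |true defect|)``: damaged locations retest
  far more variably than healthy ones, which is what drives regression to
  the mean in binned change estimates.
* **Arm-specific recovery** — at follow-up a fraction of the defect depth
  resolves, per arm and visit.
* **Floor/ceiling** — emitted sensitivities are clipped to the instrument's
  0-40 dB range.
* **Attrition** — whole-visit dropout and occasional unreliable exams
  (reliability indices drawn to fail the standard filter at a configured
  rate).

Random streams are split per purpose (patients, topography, noise,
reliability, dropout) so changing one configuration field does not reshuffle
unrelated draws; the same seed is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from . import geometry
from .metrics import Cohort, NormativeModel, SENS_MAX_DB, SENS_MIN_DB

__all__ = ["CohortConfig", "GroundTruth", "generate", "preset", "inject_uniform_change"]

_ECC_NORM = 27.2  # maximum pattern eccentricity; normalizes the gradient term


def _default_recovery() -> dict:
    return {
        "bariatric": {12: 0.55, 24: 0.60},
        "cwi": {12: 0.50, 24: 0.60},
    }


def _default_dropout() -> dict:
    return {12: 0.09, 24: 0.24}


@dataclass(frozen=True)
class CohortConfig:
    """Full parameterization of the synthetic generator.

    Demographics follow a weight-loss IIH trial population (women in their
    early thirties); severity is log-normal on the dB scale so most patients
    are mild with a heavy tail of severe fields.  All fields overridable;
    see :func:`preset` for frozen named configurations.
    """

    n_patients: int = 60
    visit_months: tuple[int, ...] = (0, 12, 24)
    arm_ratio: float = 0.5                 # fraction randomized to bariatric surgery
    acetazolamide_rate: float = 0.17       # within the community-weight (cwi) arm
    age_mean_years: float = 32.0
    age_sd_years: float = 7.8
    severity_mu: float = 1.85              # log-scale location of S_p (dB)
    severity_sigma: float = 0.75           # log-scale spread
    ecc_weight: float = 0.55
    blindspot_weight: float = 0.25
    local_noise_weight: float = 0.20
    sigma0_db: float = 1.0                 # test-retest SD at zero defect
    sigma1_per_db: float = 0.30            # SD growth per dB of defect depth
    recovery_fraction: Mapping[str, Mapping[int, float]] = field(
        default_factory=_default_recovery
    )
    dropout_prob: Mapping[int, float] = field(default_factory=_default_dropout)
    unreliable_prob: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        """Raise ValueError naming the offending field."""
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not self.visit_months or self.visit_months[0] != 0:
            raise ValueError("visit_months must start with the baseline month 0")
        for name in ("arm_ratio", "acetazolamide_rate", "unreliable_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.sigma0_db < 0 or self.sigma1_per_db < 0:
            raise ValueError("sigma0_db and sigma1_per_db must be >= 0")
        for name in ("ecc_weight", "blindspot_weight", "local_noise_weight"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for arm, by_visit in self.recovery_fraction.items():
            for v, f in by_visit.items():
                if not 0.0 <= f <= 1.0:
                    raise ValueError(f"recovery_fraction[{arm!r}][{v}]={f} outside [0, 1]")
        for v, p in self.dropout_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"dropout_prob[{v}]={p} outside [0, 1]")
        if self.age_sd_years < 0:
            raise ValueError("age_sd_years must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """True (noise-free) state emitted alongside the cohort.

    ``patients``: one row per patient (arm, severity, age, acetazolamide,
    per-visit dropout flags).  ``defects``: long table of the true defect
    depth per patient/eye/location/visit, before noise and clipping.
    """

    patients: pd.DataFrame
    defects: pd.DataFrame

    def to_csv(self, patients_path, defects_path) -> None:
        self.patients.to_csv(patients_path, index=False)
        self.defects.to_csv(defects_path, index=False)


def preset(name: str) -> CohortConfig:
    """Frozen named configurations.

    * ``null`` — zero severity and zero recovery: every field is normal up
      to measurement noise.  The no-signal reference for calibration.
    * ``mild_medical`` — a mildly affected cohort resembling medically
      managed disease: most worse-eye MDs within a [-7, -2] dB trial window.
    * ``iihwt_like`` — a 60-patient, two-arm, 0/12/24-month weight-trial
      cohort: mild centre of mass with a heavy severe tail and arm-specific
      recovery.
    """
    if name == "null":
        return CohortConfig(
            severity_mu=-np.inf,
            recovery_fraction={"bariatric": {}, "cwi": {}},
        )
    if name == "mild_medical":
        return CohortConfig(severity_mu=1.70, severity_sigma=0.45)
    if name == "iihwt_like":
        return CohortConfig()
    raise ValueError(f"unknown preset {name!r}; options: null, mild_medical, iihwt_like")


def generate(
    config: CohortConfig,
    model: NormativeModel = NormativeModel(),
) -> tuple[Cohort, GroundTruth]:
    """Draw one cohort; bit-identical for identical (config, model)."""
    config.validate()
    P = config.n_patients
    E = 2
    L = geometry.N_LOCATIONS
    visits = tuple(int(v) for v in config.visit_months)
    V = len(visits)

    streams = np.random.SeedSequence(config.seed).spawn(5)
    rng_pat = np.random.default_rng(streams[0])
    rng_topo = np.random.default_rng(streams[1])
    rng_noise = np.random.default_rng(streams[2])
    rng_rel = np.random.default_rng(streams[3])
    rng_drop = np.random.default_rng(streams[4])

    # --- patient-level draws ---
    pids = np.array([f"P{i + 1:03d}" for i in range(P)])
    n_bar = int(round(P * config.arm_ratio))
    arm = np.array(["bariatric"] * n_bar + ["cwi"] * (P - n_bar))
    rng_pat.shuffle(arm)
    age = np.clip(rng_pat.normal(config.age_mean_years, config.age_sd_years, P), 18.0, 55.0)
    severity = np.exp(config.severity_mu + config.severity_sigma * rng_pat.standard_normal(P))
    acz = (rng_pat.uniform(size=P) < config.acetazolamide_rate) & (arm == "cwi")

    # --- true defect field ---
    ecc = geometry.eccentricities()
    adj = geometry.blind_spot_adjacent_mask().astype(float)
    u = rng_topo.uniform(size=(P, E, L))
    eye_mult = rng_topo.uniform(0.8, 1.2, size=(P, E))
    shape = (
        config.ecc_weight * ecc[None, None, :] / _ECC_NORM
        + config.blindspot_weight * adj[None, None, :]
        + config.local_noise_weight * u
    )
    base_defect = -severity[:, None, None] * eye_mult[:, :, None] * shape  # (P, E, L)

    # --- per-visit attenuation ---
    atten = np.ones((P, V))
    for vi, month in enumerate(visits):
        if month == 0:
            continue
        rec = np.array(
            [config.recovery_fraction.get(a, {}).get(month, 0.0) for a in arm]
        )
        atten[:, vi] = 1.0 - rec
    defect = base_defect[:, :, :, None] * atten[:, None, None, :]  # (P, E, L, V)

    # --- measurement ---
    ages_at_visit = age[:, None] + np.array(visits)[None, :] / 12.0  # (P, V)
    normal = (
        model.c0_db
        - model.c1_db_per_deg * ecc[None, :, None]
        - model.c2_db_per_year * (ages_at_visit[:, None, None, :] - 20.0)[:, 0, :, :]
    )  # (P, L, V)
    sigma = config.sigma0_db + config.sigma1_per_db * np.abs(defect)
    eps = rng_noise.standard_normal((P, E, L, V)) * sigma
    sens = np.clip(normal[:, None, :, :] + defect + eps, SENS_MIN_DB, SENS_MAX_DB)

    # --- reliability indices ---
    fp = rng_rel.uniform(0.0, 0.12, size=(P, E, V))
    fn = rng_rel.uniform(0.0, 0.25, size=(P, E, V))
    fl = rng_rel.uniform(0.0, 0.25, size=(P, E, V))
    bad = rng_rel.uniform(size=(P, E, V)) < config.unreliable_prob
    which = rng_rel.integers(0, 3, size=(P, E, V))
    fp = np.where(bad & (which == 0), rng_rel.uniform(0.16, 0.30, size=(P, E, V)), fp)
    fn = np.where(bad & (which == 1), rng_rel.uniform(0.31, 0.50, size=(P, E, V)), fn)
    fl = np.where(bad & (which == 2), rng_rel.uniform(0.31, 0.50, size=(P, E, V)), fl)

    # --- dropout: whole visits removed, both eyes ---
    dropped = np.zeros((P, V), dtype=bool)
    for vi, month in enumerate(visits):
        p_drop = config.dropout_prob.get(month, 0.0)
        if month != 0 and p_drop > 0:
            dropped[:, vi] = rng_drop.uniform(size=P) < p_drop

    # --- assemble exam table in (patient, eye, visit) order ---
    eyes = np.array([geometry.Eye.RIGHT.value, geometry.Eye.LEFT.value])
    keep = ~np.repeat(dropped[:, None, :], E, axis=1)  # (P, E, V)
    flat = keep.ravel()
    meta = pd.DataFrame(
        {
            "patient_id": np.repeat(pids, E * V)[flat],
            "eye": np.tile(np.repeat(eyes, V), P)[flat],
            "visit_month": np.tile(np.array(visits), P * E)[flat],
            "age_years": np.repeat(ages_at_visit[:, None, :], E, axis=1).ravel()[flat],
            "fp_rate": fp.ravel()[flat],
            "fn_rate": fn.ravel()[flat],
            "fl_rate": fl.ravel()[flat],
            "arm": np.repeat(arm, E * V)[flat],
            "on_acetazolamide": np.repeat(acz, E * V)[flat],
        }
    )
    sens_rows = sens.transpose(0, 1, 3, 2).reshape(P * E * V, L)[flat]
    cohort = Cohort(meta, sens_rows)

    patients = pd.DataFrame(
        {
            "patient_id": pids,
            "arm": arm,
            "on_acetazolamide": acz,
            "age_years": age,
            "severity_db": severity,
            **{
                f"dropped_{m}": dropped[:, vi]
                for vi, m in enumerate(visits)
                if m != 0
            },
        }
    )
    defects = pd.DataFrame(
        {
            "patient_id": np.repeat(pids, E * L * V),
            "eye": np.tile(np.repeat(eyes, L * V), P),
            "loc_index": np.tile(np.repeat(np.arange(L), V), P * E),
            "visit_month": np.tile(np.array(visits), P * E * L),
            "true_defect_db": defect.ravel(),
        }
    )
    return cohort, GroundTruth(patients=patients, defects=defects)


def inject_uniform_change(
    cohort: Cohort,
    model: NormativeModel,
    delta_db: float,
    lo_db: float = -25.0,
    hi_db: float = -10.0,
    followup_month: int = 12,
    noise_sd_db: float = 2.0,
    seed: int = 0,
) -> Cohort:
    """Build a follow-up visit with a known uniform improvement injected.

    Takes the baseline exams of ``cohort`` and synthesizes a follow-up exam
    per eye whose sensitivity is the baseline measurement plus ``delta_db``
    at every location whose *measured* baseline TD lies in [lo, hi), plus
    fresh independent noise everywhere.  Because the injection conditions on
    the same measured quantity the binning uses, the expected change in that
    bin range is exactly ``delta_db`` — a validation harness for the
    change-estimation machinery, not a disease model.  Age is deliberately
    held at its baseline value so the normative surface cancels exactly in
    the change and the injected effect is unconfounded.
    """
    rng = np.random.default_rng(seed)
    base = cohort.select(cohort.meta["visit_month"].to_numpy() == 0)
    td, _ = base.deviations(model)
    in_range = (td >= lo_db) & (td < hi_db)
    sens_f = base.sens + np.where(in_range, delta_db, 0.0)
    sens_f = sens_f + rng.normal(0.0, noise_sd_db, size=sens_f.shape)
    sens_f = np.clip(sens_f, SENS_MIN_DB, SENS_MAX_DB)
    meta_f = base.meta.copy()
    meta_f["visit_month"] = followup_month
    meta = pd.concat([base.meta, meta_f], ignore_index=True)
    return Cohort(meta, np.vstack([base.sens, sens_f]))
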