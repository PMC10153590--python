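import dataclasses

import numpy as np
import pytest

from vfpoint import CohortConfig, Cohort, NormativeModel, VFExam, generate, preset
from vfpoint.geometry import Eye, N_LOCATIONS


@pytest.fixture(scope="session")
def model():
    return NormativeModel()


@pytest.fixture(scope="session")
def flat_model():
    """Normal = 30 dB everywhere, unit weights: TD is just sensitivity - 30."""
    return NormativeModel(c0_db=30.0, c1_db_per_deg=0.0, c2_db_per_year=0.0,
                          s0_db=1.0, s1_db_per_deg=0.0)


@pytest.fixture(scope="session")
def iihwt_cohort(model):
    cohort, truth = generate(dataclasses.replace(preset("iihwt_like"), seed=11), model)
    return cohort, truth


def make_exam(patient_id="P1", eye=Eye.RIGHT, visit_month=0, sens=None,
              fp=0.02, fn=0.05, fl=0.05, age=32.0, arm="cwi", acz=False):
    if sens is None:
        sens = np.full(N_LOCATIONS, 30.0)
    return VFExam(
        patient_id=patient_id, eye=eye, visit_month=visit_month, age_years=age,
        sensitivity_db=np.asarray(sens, dtype=float),
        fp_rate=fp, fn_rate=fn, fl_rate=fl, arm=arm, on_acetazolamide=acz,
    )


@pytest.fixture
def exam_factory():
    return make_exam
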