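import pytest
from hypothesis import HealthCheck, settings

from psoriscreen import load_study_cohort
from psoriscreen.model import (
    AssayMeasurement,
    BiologicCourse,
    Censor,
    CohortDataset,
    Condition,
    ConditionKind,
    PatientRecord,
    parse_analyte,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def cohort():
    """The packaged 20-patient study cohort."""
    return load_study_cohort()


def make_panel(**conc):
    """analyte -> (value, censor) map from keyword concentrations.

    A value of None marks the analyte below the detection range.
    """
    out = {}
    for label, v in conc.items():
        a = parse_analyte(label.replace("_", "-"))
        out[a] = (None, Censor.BELOW_RANGE) if v is None else (float(v), Censor.OBSERVED)
    return out


def tiny_cohort(panels: dict[str, dict[str, dict[str, float]]]) -> CohortDataset:
    """Build a minimal valid cohort from {patient: {condition: {analyte: conc}}}.

    Condition keys: "induced" plus biologic labels; concentration None
    means below range. PASI values are fixed placeholders.
    """
    patients, courses, assays = [], [], []
    for pid, conds in panels.items():
        patients.append(PatientRecord(pid, 45, "M"))
        for cond_key, analytes in conds.items():
            if cond_key == "induced":
                cond = Condition(ConditionKind.INDUCED)
            else:
                from psoriscreen.model import TROUGH_UG_ML

                cond = Condition(
                    ConditionKind.INDUCED_PLUS_BIOLOGIC, cond_key, TROUGH_UG_ML[cond_key][0]
                )
                courses.append(BiologicCourse(pid, cond_key, len(courses) + 1, 10.0, 2.0, 6.0))
            for label, v in analytes.items():
                a = parse_analyte(label)
                if v is None:
                    assays.append(AssayMeasurement(pid, cond, a, None, Censor.BELOW_RANGE))
                else:
                    assays.append(AssayMeasurement(pid, cond, a, float(v)))
    return CohortDataset(tuple(patients), tuple(courses), tuple(assays)).require_valid()
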