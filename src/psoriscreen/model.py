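"""Domain types for the ex vivo PBMC prescreening cohort.

A cohort couples three record kinds: patient demographics, biologic
treatment courses with absolute PASI outcomes, and multiplex immunoassay
measurements of culture supernatants under three condition kinds
(unstimulated control, S. pyogenes induction, induction plus a biologic
at its steady-state trough concentration).

Record types are permissive containers: invariants are checked centrally
by :func:`validate_dataset` (which reports findings) and enforced at the
I/O boundary, so that invalid records can be constructed, inspected and
reported rather than exploding at instantiation time.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "Analyte",
    "ANALYTES",
    "parse_analyte",
    "ConditionKind",
    "Condition",
    "Censor",
    "AssayMeasurement",
    "PatientRecord",
    "BiologicCourse",
    "CohortDataset",
    "BIOLOGICS",
    "TROUGH_UG_ML",
    "PASI_MAX",
    "validate_dataset",
    "CohortError",
    "ParseError",
    "ValidationError",
]

#: Upper bound of the Psoriasis Area and Severity Index scale.
PASI_MAX = 72.0


class CohortError(Exception):
    """Base class for cohort data errors."""


class ParseError(CohortError):
    """A malformed input row; carries file, line and field context."""

    def __init__(self, message: str, *, file: str = "?", line: int = 0, field: str = "?"):
        super().__init__(f"{file}:{line}: field {field!r}: {message}")
        self.file = file
        self.line = line
        self.field = field


class ValidationError(CohortError):
    """A dataset violating one or more invariants."""

    def __init__(self, findings: list[str]):
        super().__init__(
            "dataset failed validation with %d finding(s):\n  - %s"
            % (len(findings), "\n  - ".join(findings))
        )
        self.findings = list(findings)


class Analyte(str, enum.Enum):
    """The 18 analytes of the multiplex cytokine/chemokine panel."""

    IL_1B = "IL-1b"
    IL_2 = "IL-2"
    IL_4 = "IL-4"
    IL_5 = "IL-5"
    IL_6 = "IL-6"
    IL_7 = "IL-7"
    IL_8 = "IL-8"
    IL_10 = "IL-10"
    IL_12 = "IL-12"
    IL_13 = "IL-13"
    IL_17A = "IL-17A"
    IFN_G = "IFN-g"
    TNF_A = "TNF-a"
    MCP_1 = "MCP-1"
    MIP_1A = "MIP-1a"
    MIP_1B = "MIP-1b"
    PDGF_BB = "PDGF-BB"
    RANTES = "RANTES"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


ANALYTES: frozenset[Analyte] = frozenset(Analyte)

# Greek/unicode spellings commonly seen in assay exports map onto the
# canonical ASCII labels above.
_ANALYTE_ALIASES = {
    "ifn-γ": Analyte.IFN_G,
    "ifnγ": Analyte.IFN_G,
    "ifng": Analyte.IFN_G,
    "ifn-gamma": Analyte.IFN_G,
    "il-1β": Analyte.IL_1B,
    "il-1beta": Analyte.IL_1B,
    "tnf-α": Analyte.TNF_A,
    "tnf-alpha": Analyte.TNF_A,
    "mip-1α": Analyte.MIP_1A,
    "mip-1alpha": Analyte.MIP_1A,
    "mip-1β": Analyte.MIP_1B,
    "mip-1beta": Analyte.MIP_1B,
    "il13": Analyte.IL_13,
    "il4": Analyte.IL_4,
    "il17a": Analyte.IL_17A,
    "il6": Analyte.IL_6,
}


def parse_analyte(label: str) -> Analyte:
    """Resolve an analyte label to the closed 18-member panel.

    Accepts the canonical ASCII spellings (``"IFN-g"``) and common
    Greek-letter aliases (``"IFN-γ"``). Unknown labels raise ``ValueError``.
    """
    try:
        return Analyte(label)
    except ValueError:
        pass
    key = label.strip().lower()
    if key in _ANALYTE_ALIASES:
        return _ANALYTE_ALIASES[key]
    for a in Analyte:
        if a.value.lower() == key:
            return a
    raise ValueError(f"unknown analyte label {label!r}; panel is {sorted(a.value for a in Analyte)}")


class ConditionKind(str, enum.Enum):
    CONTROL = "control"
    INDUCED = "induced"
    INDUCED_PLUS_BIOLOGIC = "induced_plus_biologic"


#: Biologic abbreviations used throughout (clinical label in comments).
BIOLOGICS: tuple[str, ...] = (
    "ada",  # adalimumab (TNF-a inhibitor)
    "gol",  # golimumab (TNF-a inhibitor)
    "cer",  # certolizumab (TNF-a inhibitor)
    "ust",  # ustekinumab (IL-12/23 inhibitor)
    "ixe",  # ixekizumab (IL-17A inhibitor)
    "sec",  # secukinumab (IL-17A inhibitor)
    "gus",  # guselkumab (IL-23 inhibitor)
    "ris",  # risankizumab (IL-23 inhibitor)
)

#: Steady-state trough serum concentrations used as the in-culture dose,
#: in ug/mL. Secukinumab has two admissible doses reflecting the 150 mg
#: and 300 mg monthly regimens.
TROUGH_UG_ML: dict[str, tuple[float, ...]] = {
    "ada": (4.0,),
    "gol": (0.5,),
    "cer": (20.0,),
    "ust": (0.25,),
    "ixe": (3.5,),
    "sec": (16.7, 34.0),
    "gus": (1.2,),
    "ris": (2.0,),
}


@dataclass(frozen=True)
class Condition:
    """A culture condition: control, induced, or induced + biologic."""

    kind: ConditionKind
    biologic: Optional[str] = None
    dose_ug_ml: Optional[float] = None

    def key(self) -> tuple:
        return (self.kind.value, self.biologic)


class Censor(str, enum.Enum):
    OBSERVED = "observed"
    BELOW_RANGE = "below_range"  # "OOR<": below the assay detection range


@dataclass(frozen=True)
class AssayMeasurement:
    """One analyte concentration (pg/mL) for one patient and condition."""

    patient_id: str
    condition: Condition
    analyte: Analyte
    concentration: Optional[float]  # absent when censored
    censor: Censor = Censor.OBSERVED


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    age: int
    sex: str  # "M" | "F"
    has_pso: bool = True
    has_psa: bool = False
    comorbidities: tuple[str, ...] = ()


@dataclass(frozen=True)
class BiologicCourse:
    """One patient x biologic exposure with absolute PASI before/after.

    ``pasi_before`` is the day-0 score; ``pasi_after`` the outcome score
    selected by the timing rule (closest to the PBMC test for biologics
    with at least 180 days of exposure, otherwise day 180).
    """

    patient_id: str
    biologic: str
    order_index: int  # 1-based position in the patient's biologic sequence
    pasi_before: float
    pasi_after: float
    months_to_outcome: float
    tested_before_start: bool = False


@dataclass(frozen=True)
class CohortDataset:
    """Patients, their biologic courses, and their assay measurements."""

    patients: tuple[PatientRecord, ...]
    courses: tuple[BiologicCourse, ...]
    assays: tuple[AssayMeasurement, ...]

    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    def patient(self, patient_id: str) -> PatientRecord:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)

    def courses_for(self, patient_id: str) -> list[BiologicCourse]:
        return [c for c in self.courses if c.patient_id == patient_id]

    def panel(
        self, patient_id: str, kind: ConditionKind, biologic: Optional[str] = None
    ) -> dict[Analyte, tuple[Optional[float], Censor]]:
        """Analyte -> (concentration, censor) map for one condition."""
        out: dict[Analyte, tuple[Optional[float], Censor]] = {}
        for m in self.assays:
            if (
                m.patient_id == patient_id
                and m.condition.kind == kind
                and m.condition.biologic == biologic
            ):
                out[m.analyte] = (m.concentration, m.censor)
        return out

    def induced_panel(self, patient_id: str) -> dict[Analyte, tuple[Optional[float], Censor]]:
        return self.panel(patient_id, ConditionKind.INDUCED)

    def treated_panel(
        self, patient_id: str, biologic: str
    ) -> dict[Analyte, tuple[Optional[float], Censor]]:
        return self.panel(patient_id, ConditionKind.INDUCED_PLUS_BIOLOGIC, biologic)

    def require_valid(self) -> "CohortDataset":
        findings = validate_dataset(self)
        if findings:
            raise ValidationError(findings)
        return self


def _check_condition(cond: Condition, where: str, findings: list[str]) -> None:
    if cond.kind == ConditionKind.INDUCED_PLUS_BIOLOGIC:
        if cond.biologic is None or cond.dose_ug_ml is None:
            findings.append(f"{where}: treated condition must carry biologic and dose")
            return
        if cond.biologic not in TROUGH_UG_ML:
            findings.append(f"{where}: unknown biologic {cond.biologic!r}")
            return
        allowed = TROUGH_UG_ML[cond.biologic]
        if not any(abs(cond.dose_ug_ml - d) < 1e-9 for d in allowed):
            findings.append(
                f"{where}: dose {cond.dose_ug_ml} ug/mL does not match the trough "
                f"concentration(s) {allowed} for {cond.biologic!r}"
            )
    else:
        if cond.biologic is not None or cond.dose_ug_ml is not None:
            findings.append(f"{where}: biologic/dose only allowed for induced_plus_biologic")


def validate_dataset(ds: CohortDataset) -> list[str]:
    """Check every invariant; return one human-readable finding per violation.

    An empty list means the dataset is valid. Nothing is raised here.
    """
    findings: list[str] = []
    pids = set()
    for p in ds.patients:
        if p.patient_id in pids:
            findings.append(f"patient {p.patient_id!r}: duplicate patient_id")
        pids.add(p.patient_id)
        if not p.has_pso:
            findings.append(f"patient {p.patient_id!r}: has_pso must be true (inclusion criterion)")
        if p.sex not in ("M", "F"):
            findings.append(f"patient {p.patient_id!r}: sex must be M or F, got {p.sex!r}")

    course_keys = set()
    for c in ds.courses:
        where = f"course {c.patient_id}/{c.biologic}"
        if c.patient_id not in pids:
            findings.append(f"{where}: references unknown patient")
        if c.biologic not in TROUGH_UG_ML:
            findings.append(f"{where}: unknown biologic label")
        if (c.patient_id, c.biologic) in course_keys:
            findings.append(f"{where}: duplicate course")
        course_keys.add((c.patient_id, c.biologic))
        for name, v in (("pasi_before", c.pasi_before), ("pasi_after", c.pasi_after)):
            if not (0.0 <= v <= PASI_MAX):
                findings.append(f"{where}: {name}={v} outside the PASI scale [0, {PASI_MAX:g}]")
        if not c.months_to_outcome > 0:
            findings.append(f"{where}: months_to_outcome must be > 0")
        if c.order_index < 1:
            findings.append(f"{where}: order_index is 1-based")

    assay_keys = set()
    induced_counts: dict[str, int] = {}
    for m in ds.assays:
        where = f"assay {m.patient_id}/{m.condition.kind.value}/{m.condition.biologic}/{m.analyte.value}"
        if m.patient_id not in pids:
            findings.append(f"{where}: references unknown patient")
        _check_condition(m.condition, where, findings)
        k = (m.patient_id, m.condition.key(), m.analyte)
        if k in assay_keys:
            findings.append(f"{where}: duplicate (patient, condition, analyte)")
        assay_keys.add(k)
        if m.censor == Censor.BELOW_RANGE:
            if m.concentration is not None:
                findings.append(f"{where}: below_range measurement must have no concentration")
        else:
            if m.concentration is None:
                findings.append(f"{where}: observed measurement missing concentration")
            elif m.concentration < 0:
                findings.append(f"{where}: negative concentration")
    for m in ds.assays:
        if m.condition.kind == ConditionKind.INDUCED:
            induced_counts[m.patient_id] = 1
    for pid in pids:
        if pid not in induced_counts:
            findings.append(f"patient {pid!r}: no induced (S. pyogenes only) panel")
    return findings
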