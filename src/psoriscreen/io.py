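"""CSV / JSON serialization of cohort datasets.

The on-disk dialect is three UTF-8 comma-separated files with mandatory
header rows and ``.`` as the decimal mark; empty string means absent:

``patients.csv``
    patient_id, age, sex, pso, psa, comorbidities (``;``-joined)
``courses.csv``
    patient_id, biologic, order_index, pasi_before, pasi_after,
    months_to_outcome, tested_before_start
``assays.csv``
    patient_id, condition_kind, biologic, dose_ug_ml, analyte,
    concentration_pg_ml, censor
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Optional, Union

from .model import (
    AssayMeasurement,
    BiologicCourse,
    Censor,
    CohortDataset,
    Condition,
    ConditionKind,
    ParseError,
    PatientRecord,
    ValidationError,
    parse_analyte,
    validate_dataset,
)

__all__ = [
    "read_cohort_csv",
    "write_cohort_csv",
    "cohort_to_json",
    "cohort_from_json",
    "PATIENT_COLUMNS",
    "COURSE_COLUMNS",
    "ASSAY_COLUMNS",
]

PATIENT_COLUMNS = ["patient_id", "age", "sex", "pso", "psa", "comorbidities"]
COURSE_COLUMNS = [
    "patient_id",
    "biologic",
    "order_index",
    "pasi_before",
    "pasi_after",
    "months_to_outcome",
    "tested_before_start",
]
ASSAY_COLUMNS = [
    "patient_id",
    "condition_kind",
    "biologic",
    "dose_ug_ml",
    "analyte",
    "concentration_pg_ml",
    "censor",
]

_BOOL = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


def _rows(path: Union[str, Path], expected: list[str]):
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != expected:
            raise ParseError(
                f"header {reader.fieldnames} does not match {expected}",
                file=path.name,
                line=1,
                field="header",
            )
        for i, row in enumerate(reader, start=2):
            yield path.name, i, row


def _get(row, file, line, field, conv, required=True, default=None):
    raw = (row.get(field) or "").strip()
    if raw == "":
        if required:
            raise ParseError("missing value", file=file, line=line, field=field)
        return default
    try:
        return conv(raw)
    except (ValueError, KeyError) as exc:
        raise ParseError(str(exc) or f"bad value {raw!r}", file=file, line=line, field=field) from exc


def _bool(raw: str) -> bool:
    return _BOOL[raw.lower()]


def read_cohort_csv(
    patients_path: Union[str, Path],
    courses_path: Union[str, Path],
    assays_path: Union[str, Path],
) -> CohortDataset:
    """Read and fully validate a cohort from the three-file CSV dialect.

    Raises :class:`~psoriscreen.model.ParseError` naming file, line and
    field for malformed rows, and :class:`~psoriscreen.model.ValidationError`
    listing every invariant violation otherwise found.
    """
    patients = []
    for file, line, row in _rows(patients_path, PATIENT_COLUMNS):
        comorb = (row.get("comorbidities") or "").strip()
        patients.append(
            PatientRecord(
                patient_id=_get(row, file, line, "patient_id", str),
                age=_get(row, file, line, "age", int),
                sex=_get(row, file, line, "sex", str),
                has_pso=_get(row, file, line, "pso", _bool),
                has_psa=_get(row, file, line, "psa", _bool),
                comorbidities=tuple(s.strip() for s in comorb.split(";") if s.strip()),
            )
        )

    courses = []
    for file, line, row in _rows(courses_path, COURSE_COLUMNS):
        courses.append(
            BiologicCourse(
                patient_id=_get(row, file, line, "patient_id", str),
                biologic=_get(row, file, line, "biologic", str),
                order_index=_get(row, file, line, "order_index", int),
                pasi_before=_get(row, file, line, "pasi_before", float),
                pasi_after=_get(row, file, line, "pasi_after", float),
                months_to_outcome=_get(row, file, line, "months_to_outcome", float),
                tested_before_start=_get(row, file, line, "tested_before_start", _bool),
            )
        )

    assays = []
    for file, line, row in _rows(assays_path, ASSAY_COLUMNS):
        kind = _get(row, file, line, "condition_kind", ConditionKind)
        cond = Condition(
            kind=kind,
            biologic=_get(row, file, line, "biologic", str, required=False),
            dose_ug_ml=_get(row, file, line, "dose_ug_ml", float, required=False),
        )
        censor = _get(row, file, line, "censor", Censor, required=False, default=Censor.OBSERVED)
        assays.append(
            AssayMeasurement(
                patient_id=_get(row, file, line, "patient_id", str),
                condition=cond,
                analyte=_get(row, file, line, "analyte", parse_analyte),
                concentration=_get(
                    row, file, line, "concentration_pg_ml", float,
                    required=(censor == Censor.OBSERVED),
                ),
                censor=censor,
            )
        )

    ds = CohortDataset(patients=tuple(patients), courses=tuple(courses), assays=tuple(assays))
    findings = validate_dataset(ds)
    if findings:
        raise ValidationError(findings)
    return ds


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float):
        return repr(float(v))  # shortest representation that round-trips exactly
    return str(v)


def write_cohort_csv(ds: CohortDataset, out_dir: Union[str, Path]) -> dict[str, Path]:
    """Write ``patients.csv``/``courses.csv``/``assays.csv`` under *out_dir*."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {name: out_dir / f"{name}.csv" for name in ("patients", "courses", "assays")}

    with paths["patients"].open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(PATIENT_COLUMNS)
        for p in ds.patients:
            w.writerow(
                [p.patient_id, p.age, p.sex, _fmt(p.has_pso), _fmt(p.has_psa),
                 ";".join(p.comorbidities)]
            )
    with paths["courses"].open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(COURSE_COLUMNS)
        for c in ds.courses:
            w.writerow(
                [c.patient_id, c.biologic, c.order_index, _fmt(c.pasi_before),
                 _fmt(c.pasi_after), _fmt(c.months_to_outcome), _fmt(c.tested_before_start)]
            )
    with paths["assays"].open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(ASSAY_COLUMNS)
        for m in ds.assays:
            w.writerow(
                [m.patient_id, m.condition.kind.value, _fmt(m.condition.biologic),
                 _fmt(m.condition.dose_ug_ml), m.analyte.value, _fmt(m.concentration),
                 m.censor.value]
            )
    return paths


def cohort_to_json(ds: CohortDataset) -> str:
    """JSON export mirroring the CSV schema (one object with three arrays)."""
    doc = {
        "patients": [
            {
                "patient_id": p.patient_id, "age": p.age, "sex": p.sex,
                "pso": p.has_pso, "psa": p.has_psa,
                "comorbidities": list(p.comorbidities),
            }
            for p in ds.patients
        ],
        "courses": [
            {
                "patient_id": c.patient_id, "biologic": c.biologic,
                "order_index": c.order_index, "pasi_before": c.pasi_before,
                "pasi_after": c.pasi_after, "months_to_outcome": c.months_to_outcome,
                "tested_before_start": c.tested_before_start,
            }
            for c in ds.courses
        ],
        "assays": [
            {
                "patient_id": m.patient_id,
                "condition_kind": m.condition.kind.value,
                "biologic": m.condition.biologic,
                "dose_ug_ml": m.condition.dose_ug_ml,
                "analyte": m.analyte.value,
                "concentration_pg_ml": m.concentration,
                "censor": m.censor.value,
            }
            for m in ds.assays
        ],
    }
    return json.dumps(doc, indent=2)


def cohort_from_json(text: str) -> CohortDataset:
    doc = json.loads(text)
    patients = tuple(
        PatientRecord(
            patient_id=p["patient_id"], age=p["age"], sex=p["sex"],
            has_pso=p["pso"], has_psa=p["psa"],
            comorbidities=tuple(p.get("comorbidities", ())),
        )
        for p in doc["patients"]
    )
    courses = tuple(
        BiologicCourse(
            patient_id=c["patient_id"], biologic=c["biologic"],
            order_index=c["order_index"], pasi_before=c["pasi_before"],
            pasi_after=c["pasi_after"], months_to_outcome=c["months_to_outcome"],
            tested_before_start=c["tested_before_start"],
        )
        for c in doc["courses"]
    )
    assays = tuple(
        AssayMeasurement(
            patient_id=m["patient_id"],
            condition=Condition(
                kind=ConditionKind(m["condition_kind"]),
                biologic=m.get("biologic"),
                dose_ug_ml=m.get("dose_ug_ml"),
            ),
            analyte=parse_analyte(m["analyte"]),
            concentration=m.get("concentration_pg_ml"),
            censor=Censor(m.get("censor", "observed")),
        )
        for m in doc["assays"]
    )
    ds = CohortDataset(patients=patients, courses=courses, assays=assays)
    return ds.require_valid()
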