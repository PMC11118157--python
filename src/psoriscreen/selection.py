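"""Prescreening decision support: rank candidate biologics per patient.

The guiding principle is directional: a favorable biologic suppresses
the Th1/Th17 side (IFN-g, IL-17A, and every ratio built on them) and
spares or raises the Th2 side (IL-13, IL-4) in the patient's own
stimulated PBMCs. The composite score implemented here is this package's
own operationalization of that principle — it is an extension, not a
published formula:

    composite = mean over available indices of  s_i * r_i / scale_i

where r_i is the index's reduction rate for the candidate biologic,
s_i is +1 for indices oriented "lower is better" and -1 for IL-13/IL-4,
and scale_i is the standard deviation of that index's rates across the
patient's candidate biologics (a within-patient standardization making
indices with different dynamic ranges commensurable; an index with zero
spread contributes its raw oriented rate). Lower composite = more
favorable; ties break alphabetically by biologic label.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .indices import (
    FIXTURE_INDICES,
    IndexChangeRecord,
    build_index_change_table,
    _as_index,
)
from .model import Analyte, CohortDataset

__all__ = ["SelectionReport", "orientation_sign", "score_biologic", "rank_biologics"]


def orientation_sign(index) -> int:
    """+1 if a lower change is clinically favorable, -1 if higher is."""
    idx = _as_index(index)
    if idx.is_ratio:
        return +1
    return -1 if idx.numerator in (Analyte.IL_13, Analyte.IL_4) else +1


def score_biologic(
    rates: dict[str, Optional[float]],
    scales: dict[str, float],
) -> float:
    """Composite score for one patient x biologic from per-index rates.

    *rates* maps index label -> reduction rate (``None`` = censored,
    omitted); *scales* maps index label -> within-patient standard
    deviation of that index's rates. All indices censored is an error.
    """
    terms = []
    for label, rate in rates.items():
        if rate is None:
            continue
        s = orientation_sign(label)
        scale = scales.get(label, 0.0)
        terms.append(s * rate / scale if scale > 0 else s * rate)
    if not terms:
        raise ValueError("composite score undefined: all indices censored")
    return float(np.mean(terms))


@dataclass(frozen=True)
class SelectionReport:
    """Ranked biologics for one patient, with per-index provenance."""

    patient_id: str
    ranking: tuple[tuple[str, float], ...]  # (biologic, composite), ascending
    per_index_changes: tuple[IndexChangeRecord, ...]
    omitted: tuple[tuple[str, str], ...]  # (biologic, index label) censored pairs

    @property
    def recommended(self) -> str:
        return self.ranking[0][0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "patient_id": self.patient_id,
                "recommended": self.recommended,
                "ranking": [
                    {"biologic": b, "composite_score": s} for b, s in self.ranking
                ],
                "omitted_censored": [
                    {"biologic": b, "index": i} for b, i in self.omitted
                ],
                "per_index_changes": [
                    {
                        "biologic": r.biologic,
                        "index": r.index.label,
                        "reduction_rate": r.reduction_rate,
                        "difference": r.difference,
                        "status": r.status,
                    }
                    for r in self.per_index_changes
                ],
            },
            indent=2,
        )

    def to_text(self) -> str:
        lines = [f"Biologic ranking for patient {self.patient_id} (lower = more favorable):"]
        for pos, (b, s) in enumerate(self.ranking, 1):
            mark = "  <- recommended" if pos == 1 else ""
            lines.append(f"  {pos}. {b}  composite={s:+.3f}{mark}")
        if self.omitted:
            lines.append("  censored (omitted from scores): "
                         + ", ".join(f"{b}:{i}" for b, i in self.omitted))
        return "\n".join(lines)


def rank_biologics(
    ds: CohortDataset,
    patient_id: str,
    indices=FIXTURE_INDICES,
) -> SelectionReport:
    """Score every biologic the patient has a treated panel for.

    Requires at least two candidate panels. Deterministic: the ranking
    does not depend on input order, and exact score ties break
    alphabetically.
    """
    courses = sorted(ds.courses_for(patient_id), key=lambda c: c.biologic)
    if len(courses) < 2:
        raise ValueError(
            f"patient {patient_id!r} has {len(courses)} treated panel(s); need >= 2 to rank"
        )
    sub = CohortDataset(
        patients=tuple(p for p in ds.patients if p.patient_id == patient_id),
        courses=tuple(courses),
        assays=tuple(a for a in ds.assays if a.patient_id == patient_id),
    )
    records = build_index_change_table(sub, indices)

    by_bio: dict[str, dict[str, Optional[float]]] = {c.biologic: {} for c in courses}
    for r in records:
        by_bio[r.biologic][r.index.label] = r.reduction_rate

    # within-patient spread of each index across candidate biologics
    scales: dict[str, float] = {}
    for label in {r.index.label for r in records}:
        vals = [by_bio[b][label] for b in by_bio if by_bio[b].get(label) is not None]
        scales[label] = float(np.std(vals, ddof=1)) if len(vals) >= 2 else 0.0
        if math.isnan(scales[label]):
            scales[label] = 0.0

    scored = [(b, score_biologic(rates, scales)) for b, rates in sorted(by_bio.items())]
    ranking = tuple(sorted(scored, key=lambda bs: (bs[1], bs[0])))
    omitted = tuple(
        (r.biologic, r.index.label) for r in records if r.status == "censored"
    )
    return SelectionReport(
        patient_id=patient_id,
        ranking=ranking,
        per_index_changes=tuple(records),
        omitted=omitted,
    )
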