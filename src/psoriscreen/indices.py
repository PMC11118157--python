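"""Biomarker indices and their per-course change quantities.

An index is either a single analyte concentration or a ratio of two
analytes (e.g. the Th1/Th2 balance ``IFN-g/IL-13``). For each patient x
biologic course the index is evaluated on the S. pyogenes-induced panel
(baseline) and the induced-plus-biologic panel (treated), and summarized
as

    reduction rate       (treated - baseline) / baseline
    reduction difference  treated - baseline

so a negative value means the biologic suppressed the index ex vivo.

Censoring policy: a below-detection-range input censors the index value.
Additionally, ratio denominators below a quantification floor (default
0.1 pg/mL) censor the ratio: concentrations that close to zero sit below
the reliable region of the standard curve and produce arbitrarily large,
unstable ratios, so the ratio carries no usable signal even though the
raw concentration is still reported. Single-analyte indices are not
affected by the floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .model import Analyte, Censor, CohortDataset, ConditionKind, parse_analyte

__all__ = [
    "IndexDefinition",
    "IndexChangeRecord",
    "parse_index",
    "compute_index_value",
    "reduction_rate",
    "reduction_difference",
    "build_index_change_table",
    "change_table_frame",
    "DEFAULT_INDICES",
    "FIXTURE_INDICES",
    "DegenerateValueError",
    "RATIO_DENOMINATOR_FLOOR",
]

#: Quantification floor (pg/mL) applied to ratio denominators.
RATIO_DENOMINATOR_FLOOR = 0.1


class DegenerateValueError(ValueError):
    """A computation that would silently produce infinity."""


@dataclass(frozen=True)
class IndexDefinition:
    """A biomarker index: one analyte, or a numerator/denominator ratio."""

    label: str
    numerator: Analyte
    denominator: Optional[Analyte] = None

    def __post_init__(self):
        if self.denominator is not None and self.numerator == self.denominator:
            raise ValueError(f"index {self.label!r}: numerator equals denominator")

    @property
    def is_ratio(self) -> bool:
        return self.denominator is not None

    def analytes(self) -> tuple[Analyte, ...]:
        return (self.numerator,) if self.denominator is None else (self.numerator, self.denominator)


def parse_index(text: str) -> IndexDefinition:
    """Parse ``"IFN-g"`` or ``"IFN-g/IL-13"``-style index strings.

    The ``/`` separating numerator from denominator is the one in front
    of a valid analyte label, so analyte names containing no slash are
    unambiguous.
    """
    text = text.strip()
    if "/" in text:
        num, _, den = text.rpartition("/")
        try:
            return IndexDefinition(text, parse_analyte(num), parse_analyte(den))
        except ValueError:
            pass  # a lone analyte label containing '/' would fall through
    return IndexDefinition(text, parse_analyte(text))


def _as_index(x) -> IndexDefinition:
    return x if isinstance(x, IndexDefinition) else parse_index(str(x))


#: The six headline biomarkers plus the remaining single analytes needed
#: to cover the full association table.
DEFAULT_INDICES: tuple[str, ...] = (
    "IFN-g", "IL-13", "IL-4", "IL-17A", "IL-6",
    "IFN-g/IL-13", "IFN-g/IL-4", "IL-17A/IL-13", "IL-17A/IL-4",
)

#: The subset measurable from the packaged cohort (raw IL-17A/IL-6 values
#: are not part of the transcription).
FIXTURE_INDICES: tuple[str, ...] = (
    "IFN-g", "IL-13", "IL-4", "IFN-g/IL-13", "IFN-g/IL-4",
)


def compute_index_value(
    panel: dict[Analyte, tuple[Optional[float], Censor]],
    index: IndexDefinition,
    denominator_floor: float = RATIO_DENOMINATOR_FLOOR,
) -> Optional[float]:
    """Evaluate *index* on one analyte panel; ``None`` means censored.

    Raises ``KeyError`` if the panel lacks a referenced analyte and
    :class:`DegenerateValueError` for an observed denominator of exactly
    zero (only reachable with ``denominator_floor=0``).
    """
    index = _as_index(index)
    num_conc, num_cens = panel[index.numerator]
    if num_cens == Censor.BELOW_RANGE:
        return None
    if index.denominator is None:
        return num_conc
    den_conc, den_cens = panel[index.denominator]
    if den_cens == Censor.BELOW_RANGE or den_conc < denominator_floor:
        return None
    if den_conc == 0.0:
        raise DegenerateValueError(
            f"index {index.label!r}: observed denominator is exactly 0"
        )
    return num_conc / den_conc


def reduction_rate(baseline: float, treated: float) -> float:
    """(treated - baseline) / baseline; negative iff the index fell."""
    if baseline == 0.0 or not math.isfinite(baseline):
        raise DegenerateValueError(f"reduction rate undefined for baseline {baseline!r}")
    return (treated - baseline) / baseline


def reduction_difference(baseline: float, treated: float) -> float:
    """treated - baseline, in index units."""
    return treated - baseline


@dataclass(frozen=True)
class IndexChangeRecord:
    """Baseline/treated index values and their change for one course."""

    patient_id: str
    biologic: str
    index: IndexDefinition
    baseline: Optional[float]
    treated: Optional[float]
    reduction_rate: Optional[float]
    difference: Optional[float]
    status: str  # "complete" | "censored"


def build_index_change_table(
    ds: CohortDataset,
    indices,
    denominator_floor: float = RATIO_DENOMINATOR_FLOOR,
) -> list[IndexChangeRecord]:
    """One :class:`IndexChangeRecord` per (course x index).

    Censoring in either panel, in any referenced analyte, propagates to
    ``status="censored"`` with absent change values — mirroring how a
    below-range cell blanks the derived columns of an assay report.
    """
    defs = [_as_index(i) for i in indices]
    records: list[IndexChangeRecord] = []
    for course in ds.courses:
        base_panel = ds.induced_panel(course.patient_id)
        if not base_panel:
            raise ValueError(f"patient {course.patient_id!r} has no induced panel")
        treat_panel = ds.treated_panel(course.patient_id, course.biologic)
        for idx in defs:
            b = compute_index_value(base_panel, idx, denominator_floor)
            t = compute_index_value(treat_panel, idx, denominator_floor)
            if b is None or t is None:
                records.append(
                    IndexChangeRecord(course.patient_id, course.biologic, idx,
                                      b, t, None, None, "censored")
                )
            else:
                records.append(
                    IndexChangeRecord(course.patient_id, course.biologic, idx,
                                      b, t, reduction_rate(b, t),
                                      reduction_difference(b, t), "complete")
                )
    return records


def change_table_frame(records: list[IndexChangeRecord]) -> pd.DataFrame:
    """Long-format DataFrame of a change table (one row per course x index)."""
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "biologic": [r.biologic for r in records],
            "index": [r.index.label for r in records],
            "baseline": [r.baseline for r in records],
            "treated": [r.treated for r in records],
            "reduction_rate": [r.reduction_rate for r in records],
            "difference": [r.difference for r in records],
            "status": [r.status for r in records],
        }
    )
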