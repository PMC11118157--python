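"""PASI change quantities and the outcome-timing rule.

The clinical outcome per biologic course is summarized on the same
orientation as the biomarker change quantities:

    rate        (after - before) / before        negative = improvement
    difference   after - before                  in PASI units

The familiar clinical "relative PASI" (percent improvement, so that
PASI 90 means a 90% reduction) is the rate times -100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .model import BiologicCourse, CohortDataset
from .indices import DegenerateValueError

__all__ = [
    "PasiChange",
    "relative_pasi_improvement",
    "rounded_relative_pasi",
    "pasi_change",
    "build_pasi_table",
    "select_outcome_pasi",
]


@dataclass(frozen=True)
class PasiChange:
    patient_id: str
    biologic: str
    rate: float
    difference: float
    relative_improvement_pct: float


def relative_pasi_improvement(before: float, after: float) -> float:
    """Percent improvement from the day-0 PASI: (before - after)/before * 100."""
    if before <= 0:
        raise DegenerateValueError(f"relative PASI undefined for baseline {before!r}")
    return (before - after) / before * 100.0


def rounded_relative_pasi(before: float, after: float) -> int:
    """Integer relative PASI, rounding half away from zero (clinical style).

    Python's builtin ``round`` is banker's rounding; clinical tables round
    18.75 up to 19, hence the explicit rule.
    """
    pct = relative_pasi_improvement(before, after)
    return int(math.floor(abs(pct) + 0.5)) * (1 if pct >= 0 else -1)


def pasi_change(before: float, after: float, patient_id: str = "", biologic: str = "") -> PasiChange:
    """Rate, difference and percent improvement for one course."""
    if before <= 0:
        raise DegenerateValueError(f"PASI rate undefined for baseline {before!r}")
    rate = (after - before) / before
    return PasiChange(
        patient_id=patient_id,
        biologic=biologic,
        rate=rate,
        difference=after - before,
        relative_improvement_pct=-100.0 * rate,
    )


def build_pasi_table(ds: CohortDataset) -> list[PasiChange]:
    """One :class:`PasiChange` per course, keyed on (patient_id, biologic)."""
    return [
        pasi_change(c.pasi_before, c.pasi_after, c.patient_id, c.biologic)
        for c in ds.courses
    ]


def select_outcome_pasi(
    course: BiologicCourse,
    pbmc_test_month: float,
    pasi_series: list[tuple[float, float]],
) -> float:
    """Pick the outcome PASI from a (month, PASI) series per the timing rule.

    With at least 180 days (6 months) on the biologic at PBMC testing the
    outcome is the series value closest in time to the test; otherwise —
    including courses started after the test — it is the day-180 value,
    falling back to the closest recorded month at or after month 6 when
    month 6 itself is missing.
    """
    if not pasi_series:
        raise ValueError("empty PASI series")
    series = sorted(pasi_series)
    if not course.tested_before_start and pbmc_test_month >= 6.0:
        return min(series, key=lambda mv: (abs(mv[0] - pbmc_test_month), mv[0]))[1]
    at_or_after = [mv for mv in series if mv[0] >= 6.0]
    if not at_or_after:
        raise ValueError("no PASI recorded at or after day 180")
    return min(at_or_after, key=lambda mv: (mv[0], mv[1]))[1]
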