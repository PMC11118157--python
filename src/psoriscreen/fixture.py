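"""The packaged in-study cohort: 20 patients, 44 biologic courses.

The transcription carries, per patient, the S. pyogenes-induced panel
(IFN-g, IL-13, IL-4 in pg/mL) and, per course, the induced-plus-biologic
panel together with absolute PASI before (day 0) and after treatment.
One measurement (patient A's IL-4 under ustekinumab) is below the assay
detection range and is stored censored with no concentration.

Raw analyte concentrations are authoritative; ratio indices are always
recomputed from them rather than read from derived columns.
"""

from __future__ import annotations

from importlib import resources

from .io import read_cohort_csv
from .model import CohortDataset

__all__ = ["load_study_cohort"]

_CACHE: list[CohortDataset] = []


def load_study_cohort() -> CohortDataset:
    """Load the packaged 20-patient cohort (validated; cached)."""
    if not _CACHE:
        data = resources.files("psoriscreen").joinpath("data")
        with resources.as_file(data) as d:
            _CACHE.append(
                read_cohort_csv(d / "patients.csv", d / "courses.csv", d / "assays.csv")
            )
    return _CACHE[0]
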