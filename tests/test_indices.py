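"""Biomarker index evaluation and change quantities."""

import math

import pytest
from hypothesis import given, strategies as st

from psoriscreen import (
    build_index_change_table,
    compute_index_value,
    parse_index,
    reduction_difference,
    reduction_rate,
)
from psoriscreen.indices import DegenerateValueError, IndexDefinition, change_table_frame
from psoriscreen.model import Analyte

from conftest import make_panel, tiny_cohort

finite = st.floats(min_value=0.01, max_value=1e6, allow_nan=False)


def test_parse_index_forms():
    single = parse_index("IFN-g")
    assert not single.is_ratio and single.numerator is Analyte.IFN_G
    ratio = parse_index("IL-17A/IL-13")
    assert ratio.numerator is Analyte.IL_17A and ratio.denominator is Analyte.IL_13
    with pytest.raises(ValueError):
        IndexDefinition("x", Analyte.IL_4, Analyte.IL_4)


class TestComputeIndexValue:
    panel_A = make_panel(IFN_g=13.72, IL_13=4.19, IL_4=0.09)

    def test_ratio_on_induced_panel(self):
        v = compute_index_value(self.panel_A, parse_index("IFN-g/IL-13"))
        assert round(v, 2) == 3.27

    def test_single_analyte_is_identity(self):
        assert compute_index_value(self.panel_A, parse_index("IFN-g")) == 13.72

    def test_below_range_denominator_censors(self):
        panel = make_panel(IFN_g=11.97, IL_4=None)
        assert compute_index_value(panel, parse_index("IFN-g/IL-4")) is None

    def test_denominator_under_quantification_floor_censors(self):
        # 0.09 pg/mL sits below the reliable region of the standard curve
        assert compute_index_value(self.panel_A, parse_index("IFN-g/IL-4")) is None
        assert (
            compute_index_value(self.panel_A, parse_index("IFN-g/IL-4"), denominator_floor=0.0)
            == pytest.approx(13.72 / 0.09)
        )

    def test_missing_analyte_is_input_error(self):
        with pytest.raises(KeyError):
            compute_index_value(self.panel_A, parse_index("IL-17A"))

    def test_observed_zero_denominator_is_degenerate(self):
        panel = make_panel(IFN_g=5.0, IL_13=0.0)
        with pytest.raises(DegenerateValueError):
            compute_index_value(panel, parse_index("IFN-g/IL-13"), denominator_floor=0.0)


class TestChangeQuantities:
    def test_worked_reduction_rate(self):
        assert reduction_rate(45.8, 33.41) == pytest.approx(-0.2705, abs=5e-5)

    def test_worked_reduction_difference(self):
        assert reduction_difference(45.8, 33.41) == pytest.approx(-12.39)

    def test_no_change_is_zero(self):
        assert reduction_rate(7.3, 7.3) == 0.0
        assert reduction_difference(7.3, 7.3) == 0.0

    def test_zero_baseline_guard(self):
        with pytest.raises(DegenerateValueError):
            reduction_rate(0.0, 5.0)
        assert reduction_difference(0.0, 5.0) == 5.0

    @given(b=finite, t=finite, scale=st.floats(min_value=0.01, max_value=100))
    def test_rate_scale_invariant_difference_linear(self, b, t, scale):
        assert reduction_rate(b * scale, t * scale) == pytest.approx(
            reduction_rate(b, t), rel=1e-9
        )
        assert reduction_difference(b * scale, t * scale) == pytest.approx(
            scale * reduction_difference(b, t), rel=1e-9
        )

    @given(b=finite, t=finite)
    def test_rate_equals_difference_over_baseline(self, b, t):
        assert reduction_rate(b, t) == pytest.approx(
            reduction_difference(b, t) / b, rel=1e-12
        )


# Printed derived-ratio cells spot-checked against recomputation from the
# raw analyte columns (patient, condition biologic or None for induced,
# index, printed value).
PRINTED_RATIO_CELLS = [
    ("A", None, "IFN-g/IL-13", 3.27),
    ("B", "ada", "IFN-g/IL-13", 108.99),
    ("B", "ust", "IFN-g/IL-13", 57.27),
    ("C", None, "IFN-g/IL-13", 45.8),
    ("C", "ada", "IFN-g/IL-13", 33.41),
    ("C", None, "IFN-g/IL-4", 3.81),
    ("D", "ust", "IFN-g/IL-4", 13.93),
    ("T", None, "IFN-g/IL-13", 97.67),
    ("T", "ust", "IFN-g/IL-13", 158.9),
    ("O", "sec", "IFN-g/IL-13", 151.11),
    ("N", "gol", "IFN-g/IL-4", 19.28),
]


@pytest.mark.parametrize("pid,bio,index,printed", PRINTED_RATIO_CELLS)
def test_recomputed_ratios_match_printed_cells(cohort, pid, bio, index, printed):
    panel = cohort.induced_panel(pid) if bio is None else cohort.treated_panel(pid, bio)
    v = compute_index_value(panel, parse_index(index))
    assert round(v, 2) == pytest.approx(printed, abs=0.011)


class TestChangeTable:
    def test_fixture_table_shape_and_censoring(self, cohort):
        indices = ("IFN-g", "IL-13", "IL-4", "IFN-g/IL-13", "IFN-g/IL-4")
        records = build_index_change_table(cohort, indices)
        assert len(records) == 44 * len(indices)
        by_key = {(r.patient_id, r.biologic, r.index.label): r for r in records}
        # below-range IL-4 censors every IL-4-based index for A/ust
        assert by_key[("A", "ust", "IL-4")].status == "censored"
        assert by_key[("A", "ust", "IFN-g/IL-4")].status == "censored"
        # the induced IL-4 under the quantification floor censors the
        # ratio for A's other course too, but not the raw concentration
        assert by_key[("A", "ada", "IFN-g/IL-4")].status == "censored"
        assert by_key[("A", "ada", "IL-4")].status == "complete"
        complete = [r for r in records if r.status == "complete"]
        for r in complete:
            assert r.reduction_rate == pytest.approx((r.treated - r.baseline) / r.baseline)
            assert r.difference == pytest.approx(r.treated - r.baseline)

    def test_empty_index_list(self, cohort):
        assert build_index_change_table(cohort, []) == []

    def test_censored_records_have_absent_changes(self):
        ds = tiny_cohort(
            {"p": {"induced": {"IFN-g": 10, "IL-13": None}, "ada": {"IFN-g": 8, "IL-13": 2}}}
        )
        (rec,) = build_index_change_table(ds, ["IFN-g/IL-13"])
        assert rec.status == "censored"
        assert rec.reduction_rate is None and rec.difference is None

    def test_frame_round_trip_columns(self, cohort):
        frame = change_table_frame(build_index_change_table(cohort, ["IFN-g"]))
        assert list(frame.columns) == [
            "patient_id", "biologic", "index", "baseline", "treated",
            "reduction_rate", "difference", "status",
        ]
        assert len(frame) == 44
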