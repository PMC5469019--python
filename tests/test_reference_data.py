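"""Reference tables: stacked fees, CCRs, imputation rates, inflation indexes."""

import random
from decimal import Decimal as D

import pytest
from hypothesis import given, settings, strategies as st

from stdcost.billing_model import CostedServiceLine, CostMethod, PlaceOfService
from stdcost.errors import ReferenceBuildError, ReferenceLookupError
from stdcost.reference_data import (
    CCRProvenance,
    CostCenterReport,
    CostCenterRow,
    CrosswalkEntry,
    InflationIndexTable,
    SourceSchedule,
    build_stacked_fee_schedule,
    canonical_modifier_rules,
    compute_ccr_table,
    compute_imputation_rate,
    crosswalk_cost_center,
    inflation_index,
    lookup_ccr,
    lookup_fee,
    validate_crosswalk,
)

from conftest import make_line


# ---------------------------------------------------------------------------
# stacked fee schedule


def test_single_fee_sources_carry_the_fee_in_both_columns():
    table = build_stacked_fee_schedule(
        [(SourceSchedule.LABORATORY, [{"year": 2012, "code": "85025", "fee": D("9.25")}])]
    )
    entry = table.get(2012, "85025", "", SourceSchedule.LABORATORY)
    assert entry.facility_fee == entry.nonfacility_fee == D("9.25")


def test_empty_input_builds_empty_table():
    assert len(build_stacked_fee_schedule([])) == 0


def test_conflicting_duplicate_rows_abort_the_build():
    rows = [
        {"year": 2012, "code": "85025", "fee": D("9.25")},
        {"year": 2012, "code": "85025", "fee": D("9.50")},
    ]
    with pytest.raises(ReferenceBuildError, match="85025"):
        build_stacked_fee_schedule([(SourceSchedule.LABORATORY, rows)])
    # identical duplicates are tolerated (deduplicated)
    rows[1]["fee"] = D("9.25")
    assert len(build_stacked_fee_schedule([(SourceSchedule.LABORATORY, rows)])) == 1


def test_lookup_prefers_facility_fee_for_facility_place(mini_refs):
    fee, source = lookup_fee(mini_refs.fee_schedule, "71020", (), PlaceOfService.FACILITY, 2012)
    assert (fee, source) == (D("28.00"), SourceSchedule.PFS)
    fee, _ = lookup_fee(mini_refs.fee_schedule, "71020", (), PlaceOfService.NONFACILITY, 2012)
    assert fee == D("40.00")


def test_lookup_prefers_modifier_specific_row(mini_refs):
    fee, _ = lookup_fee(mini_refs.fee_schedule, "71020", ("26",), PlaceOfService.FACILITY, 2012)
    assert fee == D("12.00")  # the 26 (professional component) row, not the base row
    # a fee-selecting modifier without a dedicated row falls back to the base row
    fee, _ = lookup_fee(mini_refs.fee_schedule, "71020", ("TC",), PlaceOfService.NONFACILITY, 2012)
    assert fee == D("40.00")


def test_lookup_source_precedence_pfs_over_gap(mini_refs):
    # 99213 appears in both the PFS and the gap schedule; Medicare wins
    fee, source = lookup_fee(mini_refs.fee_schedule, "99213", (), PlaceOfService.NONFACILITY, 2012)
    assert (fee, source) == (D("50.00"), SourceSchedule.PFS)


def test_lookup_miss_returns_none(mini_refs):
    assert lookup_fee(mini_refs.fee_schedule, "00000", (), PlaceOfService.FACILITY, 2012) is None
    assert lookup_fee(mini_refs.fee_schedule, "99213", (), PlaceOfService.FACILITY, 1999) is None


def test_lookup_is_independent_of_input_row_order():
    rows_pfs = [{"year": 2012, "code": "10000", "fee": D("10.00")}]
    rows_gap = [{"year": 2012, "code": "10000", "fee": D("99.00")}]
    forward = build_stacked_fee_schedule(
        [(SourceSchedule.PFS, rows_pfs), (SourceSchedule.GAP, rows_gap)]
    )
    backward = build_stacked_fee_schedule(
        [(SourceSchedule.GAP, rows_gap), (SourceSchedule.PFS, rows_pfs)]
    )
    args = ("10000", (), PlaceOfService.FACILITY, 2012)
    assert lookup_fee(forward, *args) == lookup_fee(backward, *args) == (D("10.00"), SourceSchedule.PFS)


def test_canonical_modifier_table_covers_the_standard_rows():
    rules = canonical_modifier_rules()
    assert {r.modifier for r in rules} == {
        "50", "51", "62", "AS", "80", "81", "82", "QK", "QX", "QY",
        "P1", "P2", "P3", "P4", "P5", "P6",
    }
    by_mod = {r.modifier: r for r in rules}
    assert by_mod["50"].value == D("150")
    assert by_mod["62"].value == D("62.5")
    assert by_mod["P5"].value == D("3")


# ---------------------------------------------------------------------------
# cost-to-charge ratios


def _report(hospital, year, rows):
    return CostCenterReport(
        hospital_id=hospital,
        report_year=year,
        rows=tuple(CostCenterRow(n, D(c), D(ch)) for n, c, ch in rows),
    )


XWALK = [CrosswalkEntry("0360", "0360", "Operating Room")]


def test_moving_average_ccr_pools_costs_and_charges():
    """3-year ratio = Σcosts/Σcharges over the window, not a mean of yearly ratios."""
    reports = [
        _report("H1", 2010, [("Operating Room", 50, 100)]),
        _report("H1", 2011, [("Operating Room", 60, 100)]),
        _report("H1", 2012, [("Operating Room", 70, 100)]),
    ]
    table = compute_ccr_table("I", reports, XWALK, window=3, combine_hospitals=False)
    assert table.entries[(2012, "0360")] == D("180") / D("300")
    # window truncates at the series start: the first year stands alone
    assert table.entries[(2010, "0360")] == D("0.5")


def test_ccr_pooled_ratio_matches_brute_force_oracle():
    """Randomized reports: the builder agrees with an independent Σcost/Σcharge sum."""
    rng = random.Random(42)
    centers = ["Operating Room", "Laboratory", "Radiology-Diagnostic"]
    xwalk = [
        CrosswalkEntry("0360", "0360", "Operating Room"),
        CrosswalkEntry("0300", "0319", "Laboratory"),
        CrosswalkEntry("0320", "0324", "Radiology-Diagnostic"),
    ]
    for _ in range(30):
        years = list(range(2008, 2008 + rng.randint(1, 5)))
        hospitals = [f"H{i}" for i in range(rng.randint(1, 3))]
        reports = [
            _report(
                h, y,
                [(c, rng.randint(1, 500), rng.randint(1, 1000)) for c in centers],
            )
            for h in hospitals
            for y in years
        ]
        window = rng.randint(1, 4)
        table = compute_ccr_table("I", reports, xwalk, window=window)
        year = rng.choice(years)
        center = rng.choice(centers)
        code = {"Operating Room": "0360", "Laboratory": "0305", "Radiology-Diagnostic": "0321"}[center]
        # oracle: direct sums over the raw report rows in the window
        cost = sum(
            row.total_cost
            for r in reports
            if year - window < r.report_year <= year
            for row in r.rows
            if row.cost_center_name == center
        )
        charge = sum(
            row.total_charge
            for r in reports
            if year - window < r.report_year <= year
            for row in r.rows
            if row.cost_center_name == center
        )
        assert table.entries[(year, code)] == cost / charge


def test_crosswalk_maps_room_and_board_range():
    xwalk = [CrosswalkEntry("0115", "0122", "Adults and Pediatrics (General Routine Care)")]
    assert crosswalk_cost_center(xwalk, "0115") == "Adults and Pediatrics (General Routine Care)"
    assert crosswalk_cost_center(xwalk, "0122") == "Adults and Pediatrics (General Routine Care)"
    assert crosswalk_cost_center(xwalk, "0123") is None


def test_overlapping_crosswalk_ranges_rejected():
    with pytest.raises(ReferenceBuildError, match="overlap"):
        validate_crosswalk(
            [CrosswalkEntry("0100", "0120", "A"), CrosswalkEntry("0115", "0130", "B")]
        )


def test_zero_pooled_charge_aborts_build():
    reports = [_report("H1", 2012, [("Operating Room", 0, 0)])]
    with pytest.raises(ReferenceBuildError):
        compute_ccr_table("I", reports, XWALK, combine_hospitals=False)


def test_lookup_ccr_fallbacks(mini_refs):
    table = mini_refs.ccr_by_institution["INST-T"]
    assert lookup_ccr(table, "0360", 2012) == (D("0.5"), CCRProvenance.MAPPED)
    # unmapped revenue code: the year's hospital average
    assert lookup_ccr(table, "0999", 2012) == (D("0.4"), CCRProvenance.HOSPITAL_AVERAGE)
    # cost reports lag: a later service year carries the last report year forward
    assert lookup_ccr(table, "0360", 2013) == (D("0.5"), CCRProvenance.PRIOR_YEAR)
    with pytest.raises(ReferenceLookupError):
        lookup_ccr(table, "0360", 2005)


# ---------------------------------------------------------------------------
# imputation rate


def _costed(method, cost, charge):
    line = make_line(charge=D(charge), quantity=1 if D(charge) >= 0 else -1)
    return CostedServiceLine(line=line, cost_nominal=D(cost), cost_method=method)


def test_imputation_rate_hand_arithmetic():
    lines = [
        _costed(CostMethod.PFS, "80.00", "100.00"),
        _costed(CostMethod.LABORATORY, "120.00", "150.00"),
        _costed(CostMethod.ZERO_CHARGE, "0.00", "0.00"),  # excluded
        _costed(CostMethod.CCR, "10.00", "20.00"),        # hospital: not professional
    ]
    rate = compute_imputation_rate(lines, institution_id="I", year=2012)
    assert rate.rate == D("0.8")


def test_imputation_rate_requires_qualifying_lines():
    with pytest.raises(ReferenceBuildError):
        compute_imputation_rate([_costed(CostMethod.ZERO_CHARGE, "0.00", "0.00")])


def test_imputation_rate_is_a_fixpoint_on_imputed_lines():
    """Lines imputed at rate r reproduce r when the rate is recomputed from them."""
    rate = D("0.45")
    lines = [
        _costed(CostMethod.IMPUTE, str(D(charge) * rate), charge)
        for charge in ("100.00", "240.00", "-60.00")
    ]
    assert compute_imputation_rate(lines, "I", 2012).rate == rate


# ---------------------------------------------------------------------------
# inflation


def test_inflation_quotient_and_identity():
    table = InflationIndexTable(gdp_deflator_by_year={2010: D("100"), 2015: D("110")})
    assert inflation_index(table, 2010, 2015) == D("1.1")
    assert inflation_index(table, 2015, 2015) == 1
    assert inflation_index(table, 2010, 2015) * inflation_index(table, 2015, 2010) == 1


def test_inflation_missing_year_names_the_year():
    table = InflationIndexTable(gdp_deflator_by_year={2010: D("100")})
    with pytest.raises(ReferenceLookupError, match="2011"):
        table.index(2010, 2011)


@settings(derandomize=True, max_examples=60)
@given(st.lists(st.sampled_from(range(2005, 2016)), min_size=3, max_size=3))
def test_inflation_transitivity(years):
    """index(a,c) == index(a,b) x index(b,c) to within 1e-12."""
    table = InflationIndexTable(
        gdp_deflator_by_year={y: D("90") + D(y - 2005) * D("2.13") for y in range(2005, 2016)}
    )
    a, b, c = years
    direct = table.index(a, c)
    composed = table.index(a, b) * table.index(b, c)
    assert abs(direct - composed) < D("1e-12")
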