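"""Professional costing: PFS arithmetic, modifiers, anesthesia, decision tree."""

from decimal import Decimal as D

import pytest

from stdcost.billing_model import CostMethod, PlaceOfService
from stdcost.errors import ContractError, PipelineError
from stdcost.professional_costing import (
    PfsRvuSet,
    anesthesia_units,
    apply_modifier_adjustments,
    compute_pfs_fee,
    cost_anesthesia_from_charge,
    cost_anesthesia_line,
    cost_professional_line,
    impute_cost,
)
from stdcost.reference_data import canonical_modifier_rules

from conftest import make_line

RULES = canonical_modifier_rules()


# ---------------------------------------------------------------------------
# PFS relative value units


def test_pfs_fee_selects_practice_expense_by_place():
    rvus = PfsRvuSet(
        work_rvu=D("1.0"),
        practice_expense_rvu_facility=D("0.5"),
        practice_expense_rvu_nonfacility=D("1.5"),
        malpractice_rvu=D("0.1"),
        conversion_factor=D("30"),
    )
    assert compute_pfs_fee(rvus, PlaceOfService.FACILITY) == D("48.00")
    assert compute_pfs_fee(rvus, PlaceOfService.NONFACILITY) == D("78.00")
    doubled = PfsRvuSet(rvus.work_rvu, rvus.practice_expense_rvu_facility,
                        rvus.practice_expense_rvu_nonfacility, rvus.malpractice_rvu, D("60"))
    assert compute_pfs_fee(doubled, PlaceOfService.FACILITY) == 2 * D("48.00")


def test_pfs_fee_zero_rvus():
    rvus = PfsRvuSet(D(0), D(0), D(0), D(0), D("30"))
    assert compute_pfs_fee(rvus, PlaceOfService.FACILITY) == 0


# ---------------------------------------------------------------------------
# modifier percentage adjustments


@pytest.mark.parametrize(
    "modifiers, expected",
    [
        ((), D("100.00")),
        (("50",), D("150.00")),     # bilateral procedure
        (("51",), D("50.00")),      # multiple procedure
        (("62",), D("62.50")),      # cosurgeon
        (("80",), D("16.00")),      # surgery assistant
        (("AS",), D("16.00")),
        (("XX",), D("100.00")),     # unknown modifier ignored
        (("51", "62"), D("31.25")), # percentages compound multiplicatively
        (("62", "51"), D("31.25")), # … independent of order
    ],
)
def test_apply_modifier_adjustments(modifiers, expected):
    assert apply_modifier_adjustments(D("100.00"), modifiers, RULES) == expected


# ---------------------------------------------------------------------------
# anesthesia units and costs


@pytest.mark.parametrize(
    "minutes, expected_time_units",
    [(45, D("3.0")), (40, D("2.7")), (0, D("0.0")), (15, D("1.0")), (83, D("5.5"))],
)
def test_time_units_are_minutes_over_15_rounded_to_tenth(minutes, expected_time_units):
    assert anesthesia_units(0, minutes).time_units == expected_time_units


@pytest.mark.parametrize(
    "status, expected_units",
    [("P1", 0), ("P2", 0), ("P3", 1), ("P4", 2), ("P5", 3), ("P6", 0), (None, 0)],
)
def test_physical_status_units(status, expected_units):
    assert anesthesia_units(0, 0, status).physical_status_units == expected_units


def test_negative_minutes_rejected():
    with pytest.raises(ContractError):
        anesthesia_units(5, -1)


def _anesthesia_line(**overrides):
    defaults = dict(procedure_code="00100", anesthesia_minutes=D(45), charge=D("400.00"))
    defaults.update(overrides)
    return make_line(**defaults)


def test_anesthesia_unit_cost(mini_refs):
    # (base 5 + time 3.0 + status 1) x CF 20.00
    line = _anesthesia_line(modifiers=("P3",))
    assert cost_anesthesia_line(line, mini_refs.anesthesia, RULES) == D("180.00")
    # medical direction halves the cost …
    line = _anesthesia_line(modifiers=("P3", "QK"))
    assert cost_anesthesia_line(line, mini_refs.anesthesia, RULES) == D("90.00")
    # … but only once, even if two direction modifiers appear
    line = _anesthesia_line(modifiers=("P3", "QX", "QY"))
    assert cost_anesthesia_line(line, mini_refs.anesthesia, RULES) == D("90.00")


def test_anesthesia_zero_minutes(mini_refs):
    line = _anesthesia_line(procedure_code="00400", anesthesia_minutes=D(0), modifiers=("P1",))
    assert cost_anesthesia_line(line, mini_refs.anesthesia, RULES) == D("80.00")


def test_anesthesia_unknown_code_signals_fall_through(mini_refs):
    line = _anesthesia_line(procedure_code="01999")
    assert cost_anesthesia_line(line, mini_refs.anesthesia, RULES) is None


def test_charge_conversion_route():
    assert cost_anesthesia_from_charge(D("360.00"), D("40"), D("20")) == D("180.00")
    assert cost_anesthesia_from_charge(D("123.45"), D("25"), D("25")) == D("123.45")
    assert cost_anesthesia_from_charge(D("0"), D("40"), D("20")) == 0
    with pytest.raises(ContractError):
        cost_anesthesia_from_charge(D("100"), D("0"), D("20"))


def test_charge_conversion_agrees_with_unit_route(mini_refs):
    """Charges billed at the institution CF reprice to the unit-route cost within 1 cent."""
    params = mini_refs.anesthesia
    billing_cf = params.billing_cf_by_institution_year[("INST-T", 2012)]
    medicare_cf = params.conversion_factor_by_year[2012]
    for minutes, status in ((45, "P3"), (40, None), (117, "P5")):
        units = anesthesia_units(params.base_units_by_code["00100"], minutes, status)
        unit_cost = units.total * medicare_cf
        billed_charge = units.total * billing_cf
        converted = cost_anesthesia_from_charge(billed_charge, billing_cf, medicare_cf)
        assert abs(converted - unit_cost) <= D("0.01")


# ---------------------------------------------------------------------------
# imputation


@pytest.mark.parametrize(
    "charge, rate, expected",
    [(D("200.00"), D("0.45"), D("90.00")), (D("0"), D("0.45"), D("0.00")),
     (D("-100.00"), D("0.45"), D("-45.00"))],
)
def test_impute_cost(charge, rate, expected):
    assert impute_cost(charge, rate) == expected


# ---------------------------------------------------------------------------
# the decision tree


def test_zero_charge_gives_zero_cost(mini_refs):
    costed = cost_professional_line(make_line(charge=D("0.00")), mini_refs)
    assert (costed.cost_method, costed.cost_nominal) == (CostMethod.ZERO_CHARGE, 0)


def test_header_line_costed_zero(mini_refs):
    costed = cost_professional_line(make_line(header=True, charge_master_code="HDR1"), mini_refs)
    assert (costed.cost_method, costed.cost_nominal) == (CostMethod.HEADER, 0)


def test_fee_times_quantity(mini_refs):
    costed = cost_professional_line(make_line(quantity=2, charge=D("240.00")), mini_refs)
    assert (costed.cost_method, costed.cost_nominal) == (CostMethod.PFS, D("100.00"))


def test_billing_correction_gets_negative_cost(mini_refs):
    costed = cost_professional_line(make_line(quantity=-1, charge=D("-75.00")), mini_refs)
    assert costed.cost_nominal == D("-50.00")
    assert costed.cost_method is CostMethod.PFS


def test_anesthesia_route_in_tree(mini_refs):
    costed = cost_professional_line(_anesthesia_line(modifiers=("P3",)), mini_refs)
    assert (costed.cost_method, costed.cost_nominal) == (CostMethod.ANESTHESIA, D("180.00"))
    # anesthesia code without minutes: the charge-conversion route (billing CF known)
    line = _anesthesia_line(anesthesia_minutes=None, charge=D("360.00"))
    costed = cost_professional_line(line, mini_refs)
    assert (costed.cost_method, costed.cost_nominal) == (CostMethod.ANESTHESIA, D("180.00"))


def test_unmatched_code_imputes(mini_refs):
    costed = cost_professional_line(make_line(procedure_code="X9999", charge=D("200.00")), mini_refs)
    assert (costed.cost_method, costed.cost_nominal) == (CostMethod.IMPUTE, D("90.00"))


def test_zero_fee_match_falls_through_to_imputation(mini_refs):
    """A matched fee of exactly 0 counts as unmappable-to-a-non-zero-fee."""
    costed = cost_professional_line(make_line(procedure_code="77777", charge=D("100.00")), mini_refs)
    assert (costed.cost_method, costed.cost_nominal) == (CostMethod.IMPUTE, D("45.00"))


def test_missing_imputation_rate_is_a_pipeline_error(mini_refs):
    line = make_line(procedure_code="X9999", institution_id="ELSEWHERE")
    with pytest.raises(PipelineError, match="ELSEWHERE"):
        cost_professional_line(line, mini_refs)


def test_homogeneity_fee_scaling(mini_refs, refs, extract):
    """Scaling every fee by k scales every fee-schedule cost by k."""
    from stdcost.reference_data import FeeScheduleEntry, FeeScheduleTable
    import dataclasses

    lines, ledger = extract
    scaled_table = FeeScheduleTable(
        FeeScheduleEntry(
            year=e.year, code=e.code, modifier=e.modifier,
            nonfacility_fee=2 * e.nonfacility_fee, facility_fee=2 * e.facility_fee,
            source_schedule=e.source_schedule,
        )
        for e in refs.fee_schedule.sorted_entries()
    )
    scaled_refs = dataclasses.replace(refs, fee_schedule=scaled_table)
    fee_methods = {CostMethod.PFS, CostMethod.LABORATORY, CostMethod.DME,
                   CostMethod.DRUG, CostMethod.GAP}
    checked = 0
    for line, entry in zip(lines[:300], ledger[:300]):
        if entry.expected_method not in fee_methods:
            continue
        base = cost_professional_line(line, refs).cost_nominal
        scaled = cost_professional_line(line, scaled_refs).cost_nominal
        # equal up to the final cent rounding, which does not commute with scaling
        assert abs(scaled - 2 * base) <= D("0.01")
        checked += 1
    assert checked > 20
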