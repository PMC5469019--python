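"""Billing domain types and delimited interchange round trips."""

import datetime as dt
from decimal import Decimal as D

import pytest

from stdcost.billing_model import (
    ClaimForm,
    CohortRequest,
    CostedServiceLine,
    CostMethod,
    EpisodeRecord,
    filter_final_billed,
    read_billing_extract,
    read_costed_lines,
    write_billing_extract,
    write_costed_lines,
)
from stdcost.errors import ContractError, FormatError
from stdcost.fixtures import FIXTURE_DIALECT

from conftest import make_line


def test_extract_round_trip(tmp_path, extract):
    """Writing then reading a generated extract reproduces every field of every line."""
    lines, _ = extract
    path = tmp_path / "extract.csv"
    write_billing_extract(lines, path)
    result = read_billing_extract(path, FIXTURE_DIALECT)
    assert result.rejected == []
    assert result.lines == lines


def test_missing_mandatory_column_is_a_format_error(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("patient_id,service_date\nPT1,2012-01-01\n")
    with pytest.raises(FormatError, match="charge"):
        read_billing_extract(path)


def test_invalid_rows_are_reported_not_dropped(tmp_path):
    """Rows violating invariants are rejected with their line number; valid rows survive."""
    good = make_line()
    path = tmp_path / "extract.csv"
    write_billing_extract([good], path)
    text = path.read_text().rstrip("\n")
    rows = [
        # 5 modifiers (at most 4 modifier fields exist on a claim)
        text.splitlines()[1].replace(",,nonfacility", ",50;51;62;80;82,nonfacility"),
        # charge and quantity disagreeing in sign (not a valid billing correction)
        text.splitlines()[1].replace(",1,120.00", ",-1,120.00"),
        # unparseable date
        text.splitlines()[1].replace("2012-06-01", "June 1 2012"),
    ]
    path.write_text(text + "\n" + "\n".join(rows) + "\n")
    result = read_billing_extract(path)
    assert len(result.lines) == 1
    assert len(result.rejected) == 3  # nothing silently lost
    line_numbers = [n for n, _ in result.rejected]
    assert line_numbers == [3, 4, 5]


@pytest.mark.parametrize("n_lines", [0, 10])
def test_costed_round_trip(tmp_path, n_lines):
    """Costed output round-trips exactly, including negative (correction) costs."""
    lines = []
    for i in range(n_lines):
        sign = -1 if i % 3 == 0 else 1
        line = make_line(
            line_id=f"L{i}", quantity=sign, charge=sign * D("75.00"),
        )
        lines.append(
            CostedServiceLine(
                line=line,
                cost_nominal=sign * D("50.00"),
                cost_method=CostMethod.PFS,
                cost_inflated=sign * D("52.50"),
                inflation_target_year=2015,
            )
        )
    path = tmp_path / "costed.csv"
    write_costed_lines(lines, path)
    back = read_costed_lines(path)
    assert back == lines
    if n_lines == 0:  # empty list still produces a header-only file
        assert path.read_text().count("\n") == 1


def test_costed_writer_rejects_mixed_target_years(tmp_path):
    a = CostedServiceLine(line=make_line(), cost_nominal=D("1.00"),
                          cost_method=CostMethod.PFS, cost_inflated=D("1.00"),
                          inflation_target_year=2014)
    b = CostedServiceLine(line=make_line(line_id="L2"), cost_nominal=D("1.00"),
                          cost_method=CostMethod.PFS, cost_inflated=D("1.00"),
                          inflation_target_year=2015)
    with pytest.raises(ContractError):
        write_costed_lines([a, b], tmp_path / "x.csv")


@pytest.mark.parametrize(
    "flags, expected",
    [((True, True, False, True, False), 3), ((True, True), 2), ((False, False), 0)],
)
def test_filter_final_billed(flags, expected):
    lines = [make_line(line_id=f"L{i}", final_billed=f) for i, f in enumerate(flags)]
    kept = filter_final_billed(lines)
    assert len(kept) == expected
    assert all(l.final_billed for l in kept)


def test_service_line_invariants():
    with pytest.raises(ValueError, match="none of"):
        make_line(procedure_code=None, ub_revenue_code=None, charge_master_code=None).validate()
    with pytest.raises(ValueError, match="modifiers"):
        make_line(modifiers=("50", "51", "62", "80", "82")).validate()
    with pytest.raises(ValueError, match="sign"):
        make_line(quantity=-1, charge=D("10.00")).validate()
    # zero charge or zero quantity is compatible with either sign
    make_line(quantity=-1, charge=D("0.00")).validate()


def test_costed_line_sign_invariant():
    with pytest.raises(ValueError, match="sign"):
        CostedServiceLine(
            line=make_line(quantity=-1, charge=D("-10.00")),
            cost_nominal=D("5.00"),
            cost_method=CostMethod.PFS,
        )


def test_episode_and_request_invariants():
    with pytest.raises(ValueError):
        EpisodeRecord(
            patient_id="P", episode_id="E",
            admission_date=dt.date(2012, 5, 2), discharge_date=dt.date(2012, 5, 1),
        )
    with pytest.raises(ValueError):
        CohortRequest(
            patient_ids=frozenset({"P"}),
            date_ranges=(dt.date(2012, 2, 1), dt.date(2012, 1, 1)),
            target_year=2012,
        )
    req = CohortRequest(
        patient_ids=frozenset({"P"}),
        date_ranges={"P": (dt.date(2012, 1, 1), dt.date(2012, 6, 30))},
        target_year=2012,
    )
    assert req.covers("P", dt.date(2012, 3, 1))
    assert not req.covers("P", dt.date(2012, 7, 1))
    assert not req.covers("Q", dt.date(2012, 3, 1))


def test_hospital_routing():
    prof = make_line()
    assert not prof.is_hospital()
    hosp = make_line(claim_form=ClaimForm.HOSPITAL, ub_revenue_code="0360")
    assert hosp.is_hospital()
    # absent a claim form, a UB revenue code marks the facility bill
    inferred = make_line(claim_form=None, ub_revenue_code="0360")
    assert inferred.is_hospital()
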