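"""Shared fixtures: a seeded synthetic warehouse and a small hand-built bundle."""

from __future__ import annotations

import datetime as dt
from decimal import Decimal as D

import pytest

from stdcost.billing_model import ClaimForm, PlaceOfService, ServiceLine
from stdcost.fixtures import (
    FixtureSpec,
    generate_billing_extract,
    generate_reference_bundle,
)
from stdcost.reference_data import (
    AnesthesiaParams,
    CCRTable,
    InflationIndexTable,
    ReferenceBundle,
    SourceSchedule,
    build_stacked_fee_schedule,
    canonical_modifier_rules,
)


@pytest.fixture(scope="session")
def spec() -> FixtureSpec:
    return FixtureSpec(seed=20240915, n_lines=1000)


@pytest.fixture(scope="session")
def refs(spec):
    return generate_reference_bundle(spec)


@pytest.fixture(scope="session")
def extract(spec, refs):
    """(service lines, expected-cost ledger) for the session fixture spec."""
    return generate_billing_extract(spec, refs)


@pytest.fixture(scope="session")
def mini_refs() -> ReferenceBundle:
    """A tiny hand-built bundle with known fees, ratios, and rates (year 2012)."""
    fee_schedule = build_stacked_fee_schedule(
        [
            (
                SourceSchedule.PFS,
                [
                    {"year": 2012, "code": "99213", "nonfacility_fee": D("50.00"),
                     "facility_fee": D("50.00")},
                    {"year": 2012, "code": "71020", "nonfacility_fee": D("40.00"),
                     "facility_fee": D("28.00")},
                    {"year": 2012, "code": "71020", "modifier": "26",
                     "nonfacility_fee": D("12.00"), "facility_fee": D("12.00")},
                    {"year": 2012, "code": "77777", "fee": D("0.00")},  # zero-fee match
                ],
            ),
            (SourceSchedule.LABORATORY, [{"year": 2012, "code": "85025", "fee": D("9.25")}]),
            (SourceSchedule.GAP, [{"year": 2012, "code": "99213", "fee": D("33.00")}]),
        ]
    )
    return ReferenceBundle(
        fee_schedule=fee_schedule,
        modifier_rules=canonical_modifier_rules(),
        anesthesia=AnesthesiaParams(
            base_units_by_code={"00100": D(5), "00400": D(4)},
            conversion_factor_by_year={2012: D("20.00")},
            billing_cf_by_institution_year={("INST-T", 2012): D("40.00")},
        ),
        imputation_rates={("INST-T", 2012): D("0.45")},
        ccr_by_institution={
            "INST-T": CCRTable(
                institution_id="INST-T",
                entries={(2012, "0360"): D("0.5"), (2012, "0300"): D("0.25")},
                hospital_average={2012: D("0.4")},
            )
        },
        inflation=InflationIndexTable(
            gdp_deflator_by_year={2010: D("100"), 2012: D("105"), 2015: D("110")}
        ),
    )


def make_line(**overrides) -> ServiceLine:
    """A valid professional line with sensible defaults, overridable per test."""
    defaults = dict(
        line_id="L1",
        patient_id="PT00001",
        institution_id="INST-T",
        service_date=dt.date(2012, 6, 1),
        charge_master_code="CM1",
        procedure_code="99213",
        modifiers=(),
        place_of_service=PlaceOfService.NONFACILITY,
        quantity=1,
        charge=D("120.00"),
        claim_form=ClaimForm.PROFESSIONAL,
    )
    defaults.update(overrides)
    return ServiceLine(**defaults)
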