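"""Professional (CMS-1500) service costing.

The decision tree, in order:

1. header-flagged lines cost zero with method ``header``;
2. zero-charge lines cost zero with method ``zero_charge``;
3. anesthesia codes are costed from base + time + physical-status units times
   the year's conversion factor (or from the charge via billing/Medicare
   conversion factors when minutes are unavailable);
4. a fee-schedule match with a non-zero fee gives cost = fee × |quantity| ×
   modifier percentages, signed like the quantity, with the source schedule
   as the method;
5. anything left is imputed: charge × the institution-year's average
   professional cost-to-charge rate.

A matched fee of exactly zero counts as "cannot be mapped to a non-zero fee"
and falls through to imputation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal
from typing import Sequence

from ._money import D, round_cents, round_tenth, sign
from .billing_model import CostedServiceLine, CostMethod, PlaceOfService, ServiceLine
from .errors import ContractError, PipelineError
from .reference_data import (
    AnesthesiaParams,
    ModifierRule,
    ModifierService,
    ReferenceBundle,
    RuleKind,
    lookup_fee,
)

log = logging.getLogger(__name__)

#: ASA physical-status modifier → units added to the anesthesia base
PHYSICAL_STATUS_UNITS = {
    "P1": Decimal(0),
    "P2": Decimal(0),
    "P3": Decimal(1),
    "P4": Decimal(2),
    "P5": Decimal(3),
    "P6": Decimal(0),
}


@dataclass(frozen=True)
class PfsRvuSet:
    """Physician Fee Schedule relative value units for one service.

    The fee is (work + practice expense + malpractice) × conversion factor;
    the practice-expense component depends on place of service because the
    allowable practice expense is lower where the facility bills separately.
    """

    work_rvu: Decimal
    practice_expense_rvu_facility: Decimal
    practice_expense_rvu_nonfacility: Decimal
    malpractice_rvu: Decimal
    conversion_factor: Decimal

    def __post_init__(self) -> None:
        for component in (
            self.work_rvu,
            self.practice_expense_rvu_facility,
            self.practice_expense_rvu_nonfacility,
            self.malpractice_rvu,
        ):
            if component < 0:
                raise ValueError("RVU components must be non-negative")
        if self.conversion_factor <= 0:
            raise ValueError("conversion factor must be positive")


def compute_pfs_fee(rvus: PfsRvuSet, place_of_service: PlaceOfService) -> Decimal:
    """Sum the RVUs (selecting practice expense by place) times the conversion factor."""
    pe = (
        rvus.practice_expense_rvu_facility
        if place_of_service is PlaceOfService.FACILITY
        else rvus.practice_expense_rvu_nonfacility
    )
    total = rvus.work_rvu + pe + rvus.malpractice_rvu
    return round_cents(total * rvus.conversion_factor)


def apply_modifier_adjustments(
    fee: Decimal, modifiers: Sequence[str], rules: Sequence[ModifierRule]
) -> Decimal:
    """Apply every percent-of-fee rule whose modifier appears on the line.

    Multiple percentages compound multiplicatively, so the result is
    independent of modifier order.  Modifiers without a matching rule are
    ignored; each rule fires at most once per line.
    """
    if fee < 0:
        raise ContractError("fee must be non-negative before modifier adjustment")
    result = D(fee)
    present = set(modifiers)
    for rule in rules:
        if rule.rule_kind is RuleKind.PERCENT_OF_FEE and rule.modifier in present:
            result *= rule.value / 100
    return round_cents(result)


@dataclass(frozen=True)
class AnesthesiaUnits:
    """Base + time + physical-status anesthesia units for one line."""

    base_units: Decimal
    time_units: Decimal  # minutes / 15, rounded to 0.1
    physical_status_units: Decimal

    @property
    def total(self) -> Decimal:
        return self.base_units + self.time_units + self.physical_status_units


def anesthesia_units(
    base_units: Decimal | int,
    minutes: Decimal | int,
    physical_status_modifier: str | None = None,
) -> AnesthesiaUnits:
    """Assemble anesthesia units: time = minutes/15 rounded to 0.1; status from P1–P6."""
    minutes = D(minutes)
    if minutes < 0:
        raise ContractError("anesthesia minutes must be non-negative")
    time_units = round_tenth(minutes / 15)
    status_units = PHYSICAL_STATUS_UNITS.get(physical_status_modifier or "", Decimal(0))
    return AnesthesiaUnits(
        base_units=D(base_units), time_units=time_units, physical_status_units=status_units
    )


def _direction_reduction(modifiers: Sequence[str], rules: Sequence[ModifierRule]) -> Decimal:
    """50% medical-direction reduction: applied once even if several of QK/QX/QY appear."""
    present = set(modifiers)
    for rule in rules:
        if (
            rule.service_type is ModifierService.ANESTHESIA
            and rule.rule_kind is RuleKind.PERCENT_OF_FEE
            and rule.modifier in present
        ):
            return rule.value / 100
    return Decimal(1)


def _status_modifier(modifiers: Sequence[str]) -> str | None:
    for m in modifiers:
        if m in PHYSICAL_STATUS_UNITS:
            return m
    return None


def cost_anesthesia_line(
    line: ServiceLine, params: AnesthesiaParams, rules: Sequence[ModifierRule]
) -> Decimal | None:
    """Unit-based anesthesia cost for one line; ``None`` signals fall-through.

    cost = (base + time + status units) × conversion_factor(year), reduced by
    50% at most once when a medical-direction modifier (QK/QX/QY) is present,
    then scaled by |quantity| and signed like the quantity.  Returns ``None``
    when the code has no base units or the year has no conversion factor, so
    the caller can fall through to the imputation path.
    """
    code = line.procedure_code
    if code is None or code not in params.base_units_by_code:
        return None
    if line.anesthesia_minutes is None:
        return None
    cf = params.conversion_factor_by_year.get(line.service_year)
    if cf is None:
        return None
    units = anesthesia_units(
        params.base_units_by_code[code], line.anesthesia_minutes, _status_modifier(line.modifiers)
    )
    reduction = _direction_reduction(line.modifiers, rules)
    magnitude = units.total * cf * reduction * abs(line.quantity)
    line_sign = sign(line.quantity) or sign(line.charge) or 1
    return round_cents(magnitude) * line_sign


def cost_anesthesia_from_charge(
    charge: Decimal, billing_conversion_factor: Decimal, medicare_conversion_factor: Decimal
) -> Decimal:
    """Charge-conversion anesthesia route: charge / billing CF × Medicare CF.

    The billed charge is billed units × the institution's billing conversion
    factor, so dividing recovers the units and multiplying reprices them at
    the Medicare rate.  Any medical-direction reduction is already reflected
    in the billed units, so no further reduction is applied here.
    """
    if billing_conversion_factor <= 0:
        raise ContractError("billing conversion factor must be positive")
    return round_cents(D(charge) / billing_conversion_factor * medicare_conversion_factor)


def impute_cost(charge: Decimal, rate: Decimal) -> Decimal:
    """Imputed cost: charge × average professional cost-to-charge rate (sign follows charge)."""
    if rate <= 0:
        raise ContractError("imputation rate must be strictly positive")
    return round_cents(D(charge) * rate)


def _fee_schedule_rules(rules: Sequence[ModifierRule]) -> list[ModifierRule]:
    return [r for r in rules if r.service_type is ModifierService.FEE_SCHEDULE]


def cost_professional_line(line: ServiceLine, refs: ReferenceBundle) -> CostedServiceLine:
    """Run one professional line through the costing decision tree."""
    if line.header:
        return CostedServiceLine(line=line, cost_nominal=Decimal("0.00"), cost_method=CostMethod.HEADER)
    if line.charge == 0:
        return CostedServiceLine(
            line=line, cost_nominal=Decimal("0.00"), cost_method=CostMethod.ZERO_CHARGE
        )

    if refs.is_anesthesia_code(line.procedure_code):
        cost = cost_anesthesia_line(line, refs.anesthesia, refs.modifier_rules)
        if cost is not None:
            return CostedServiceLine(line=line, cost_nominal=cost, cost_method=CostMethod.ANESTHESIA)
        billing_cf = refs.anesthesia.billing_cf_by_institution_year.get(
            (line.institution_id, line.service_year)
        )
        medicare_cf = refs.anesthesia.conversion_factor_by_year.get(line.service_year)
        if billing_cf is not None and medicare_cf is not None:
            cost = cost_anesthesia_from_charge(line.charge, billing_cf, medicare_cf)
            return CostedServiceLine(line=line, cost_nominal=cost, cost_method=CostMethod.ANESTHESIA)
        # no units and no billing CF: fall through to fee lookup / imputation

    if line.procedure_code is not None:
        hit = lookup_fee(
            refs.fee_schedule,
            line.procedure_code,
            line.modifiers,
            line.place_of_service,
            line.service_year,
        )
        if hit is not None and hit[0] > 0:
            fee, source = hit
            adjusted = apply_modifier_adjustments(
                fee * abs(line.quantity), line.modifiers, _fee_schedule_rules(refs.modifier_rules)
            )
            line_sign = sign(line.quantity) or sign(line.charge) or 1
            return CostedServiceLine(
                line=line,
                cost_nominal=round_cents(adjusted) * line_sign,
                cost_method=source.cost_method,
            )

    rate = refs.imputation_rate(line.institution_id, line.service_year)
    if rate is None:
        raise PipelineError(
            f"no imputation rate for institution {line.institution_id!r}, "
            f"year {line.service_year}"
        )
    return CostedServiceLine(
        line=line, cost_nominal=impute_cost(line.charge, rate), cost_method=CostMethod.IMPUTE
    )
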