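"""Reference tables: stacked fee schedules, modifier rules, anesthesia
parameters, imputation rates, cost-to-charge ratios, and inflation indexes.

Professional fees come from the Medicare Physician Fee Schedule (PFS), the
clinical laboratory schedule, the DMEPOS and parenteral/enteral nutrition
(PEN) schedules, the Part B drug average-sales-price file, and a commercial
gap-code schedule for carrier-priced codes.  All of them are stacked into one
table keyed by (year, code, modifier, source schedule).  Only the PFS and gap
schedules distinguish facility from nonfacility fees; for the other sources
the same fee is carried in both columns.

Hospital costing uses cost-center-level cost-to-charge ratios (CCRs) computed
from annual cost reports, resolved through a UB-revenue-code → cost-center
crosswalk, pooled over a moving window of report years.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field
from decimal import Decimal
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from ._money import D
from .billing_model import CostedServiceLine, CostMethod, FEE_BASED_METHODS, PlaceOfService
from .errors import ReferenceBuildError, ReferenceLookupError

log = logging.getLogger(__name__)


class SourceSchedule(str, Enum):
    PFS = "PFS"
    LABORATORY = "laboratory"
    DME = "DME"
    PEN = "PEN"
    DRUG = "drug"
    GAP = "gap"

    @property
    def cost_method(self) -> CostMethod:
        # PEN is part of the DMEPOS family; the method taxonomy has no PEN label
        if self is SourceSchedule.PEN:
            return CostMethod.DME
        return CostMethod(self.value)


#: lookup precedence when one code appears in several schedules: Medicare
#: schedules are consulted before the commercial gap file.
SOURCE_PRECEDENCE: tuple[SourceSchedule, ...] = (
    SourceSchedule.PFS,
    SourceSchedule.LABORATORY,
    SourceSchedule.DME,
    SourceSchedule.PEN,
    SourceSchedule.DRUG,
    SourceSchedule.GAP,
)

#: modifiers that select a distinct fee row rather than a percentage
FEE_SELECTING_MODIFIERS: tuple[str, ...] = ("26", "TC", "53")


@dataclass(frozen=True)
class FeeScheduleEntry:
    year: int
    code: str
    modifier: str  # "" (base row) or one of 26 / TC / 53
    nonfacility_fee: Decimal
    facility_fee: Decimal
    source_schedule: SourceSchedule

    def __post_init__(self) -> None:
        if self.nonfacility_fee < 0 or self.facility_fee < 0:
            raise ValueError("fees must be non-negative")

    @property
    def key(self) -> tuple[int, str, str, SourceSchedule]:
        return (self.year, self.code, self.modifier, self.source_schedule)

    def fee_for(self, place: PlaceOfService) -> Decimal:
        return self.facility_fee if place is PlaceOfService.FACILITY else self.nonfacility_fee


class FeeScheduleTable:
    """Stacked multi-source fee schedule with deterministic lookup."""

    def __init__(self, entries: Iterable[FeeScheduleEntry]):
        self._entries: dict[tuple[int, str, str, SourceSchedule], FeeScheduleEntry] = {}
        for entry in entries:
            self._entries[entry.key] = entry

    def __len__(self) -> int:
        return len(self._entries)

    def sorted_entries(self) -> list[FeeScheduleEntry]:
        """Entries arranged first by year, then code, then modifier (file order)."""
        return sorted(
            self._entries.values(),
            key=lambda e: (e.year, e.code, e.modifier, e.source_schedule.value),
        )

    @property
    def years(self) -> set[int]:
        return {e.year for e in self._entries.values()}

    def get(self, year: int, code: str, modifier: str, source: SourceSchedule):
        return self._entries.get((year, code, modifier, source))


def build_stacked_fee_schedule(
    per_source_tables: Sequence[tuple[SourceSchedule, Sequence[Mapping[str, object]]]],
) -> FeeScheduleTable:
    """Stack per-source fee tables into one table.

    Each row mapping needs ``year``, ``code`` and either a single ``fee``
    column (sources without a facility split: the fee is carried in both
    columns) or ``nonfacility_fee``/``facility_fee``; an optional ``modifier``
    column carries 26/TC/53 rows.  Duplicate (year, code, modifier, source)
    keys with conflicting fees abort the build with the full collision list.
    """
    entries: dict[tuple, FeeScheduleEntry] = {}
    collisions: list[str] = []
    for source, rows in per_source_tables:
        source = SourceSchedule(source)
        for row in rows:
            if "fee" in row:
                nonfac = fac = D(row["fee"])
            else:
                nonfac = D(row["nonfacility_fee"])
                fac = D(row["facility_fee"])
            entry = FeeScheduleEntry(
                year=int(row["year"]),
                code=str(row["code"]),
                modifier=str(row.get("modifier", "") or ""),
                nonfacility_fee=nonfac,
                facility_fee=fac,
                source_schedule=source,
            )
            prior = entries.get(entry.key)
            if prior is not None:
                if (prior.nonfacility_fee, prior.facility_fee) != (nonfac, fac):
                    collisions.append(f"{entry.key}: {prior.nonfacility_fee}/{prior.facility_fee} vs {nonfac}/{fac}")
                else:
                    log.debug("duplicate identical fee row %s", entry.key)
                continue
            entries[entry.key] = entry
    if collisions:
        raise ReferenceBuildError(
            "conflicting duplicate fee rows:\n" + "\n".join(collisions)
        )
    return FeeScheduleTable(entries.values())


def lookup_fee(
    table: FeeScheduleTable,
    code: str,
    modifiers: Sequence[str],
    place_of_service: PlaceOfService,
    year: int,
) -> tuple[Decimal, SourceSchedule] | None:
    """Resolve a fee for (code, modifiers, place, year); ``None`` if unmatched.

    If any of the fee-selecting modifiers (26, TC, 53) appears on the line and
    a modifier-specific row exists, that row is preferred over the base row.
    Sources are consulted in fixed precedence order, so the result does not
    depend on input row order.
    """
    selecting = [m for m in FEE_SELECTING_MODIFIERS if m in modifiers]
    for source in SOURCE_PRECEDENCE:
        for modifier in (*selecting, ""):
            entry = table.get(year, code, modifier, source)
            if entry is not None:
                return entry.fee_for(place_of_service), source
    return None


# ---------------------------------------------------------------------------
# modifier rules (the canonical "modifiers that affect cost" table)


class RuleKind(str, Enum):
    PERCENT_OF_FEE = "percent_of_fee"
    ADD_BASE_UNITS = "add_base_units"


class ModifierService(str, Enum):
    FEE_SCHEDULE = "fee_schedule"  # physician fee and gap schedules
    ANESTHESIA = "anesthesia"


@dataclass(frozen=True)
class ModifierRule:
    modifier: str
    service_type: ModifierService
    rule_kind: RuleKind
    value: Decimal  # percent for percent_of_fee, unit count for add_base_units

    def __post_init__(self) -> None:
        if self.rule_kind is RuleKind.PERCENT_OF_FEE:
            if not (0 < self.value <= 200):
                raise ValueError(f"percent value {self.value} outside (0, 200]")
        else:
            if self.value not in (Decimal(0), Decimal(1), Decimal(2), Decimal(3)):
                raise ValueError(f"unit addend {self.value} not in {{0,1,2,3}}")


def canonical_modifier_rules() -> list[ModifierRule]:
    """The standard cost-affecting modifier table.

    Covers the bilateral / multiple-procedure / cosurgeon / surgery-assistant
    percentages, the anesthesia medical-direction 50% reductions (QK, QX, QY),
    and the ASA physical-status unit addends P1–P6.
    """
    pct = lambda m, svc, v: ModifierRule(m, svc, RuleKind.PERCENT_OF_FEE, D(v))
    units = lambda m, v: ModifierRule(m, ModifierService.ANESTHESIA, RuleKind.ADD_BASE_UNITS, D(v))
    fee = ModifierService.FEE_SCHEDULE
    anes = ModifierService.ANESTHESIA
    rules = [
        pct("50", fee, "150"),    # bilateral procedure
        pct("51", fee, "50"),     # multiple procedure
        pct("62", fee, "62.5"),   # cosurgeon
    ]
    rules += [pct(m, fee, "16") for m in ("AS", "80", "81", "82")]  # surgery assistant
    rules += [pct(m, anes, "50") for m in ("QK", "QX", "QY")]      # medical direction
    rules += [units(f"P{i}", v) for i, v in ((1, 0), (2, 0), (3, 1), (4, 2), (5, 3), (6, 0))]
    return rules


# ---------------------------------------------------------------------------
# anesthesia parameters


@dataclass(frozen=True)
class AnesthesiaParams:
    """Base units by anesthesia CPT-4 code and conversion factors by year.

    ``conversion_factor_by_year`` is the national-average Medicare dollars per
    anesthesia unit.  ``billing_cf_by_institution_year`` optionally carries the
    institution's own billing conversion factor, enabling the charge-conversion
    route for lines without recorded minutes.
    """

    base_units_by_code: Mapping[str, Decimal]
    conversion_factor_by_year: Mapping[int, Decimal]
    billing_cf_by_institution_year: Mapping[tuple[str, int], Decimal] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        for year, cf in self.conversion_factor_by_year.items():
            if cf <= 0:
                raise ValueError(f"conversion factor for {year} must be positive")


@dataclass(frozen=True)
class ImputationRate:
    institution_id: str
    year: int
    rate: Decimal

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("imputation rate must be strictly positive")


def compute_imputation_rate(
    costed_lines: Sequence[CostedServiceLine],
    institution_id: str | None = None,
    year: int | None = None,
) -> ImputationRate:
    """Average professional cost-to-charge ratio for one institution-year.

    rate = Σ assigned fee-based costs / Σ charges over professional lines
    costed by a fee schedule or the anesthesia route, excluding zero-charge
    lines.  Applied later to unmapped services' charges.  Already-imputed
    lines also qualify, which makes the construction a fixpoint: recosting
    imputed lines with the derived rate reproduces the rate.
    """
    qualifying = FEE_BASED_METHODS | {CostMethod.IMPUTE}
    total_cost = Decimal(0)
    total_charge = Decimal(0)
    insts, years = set(), set()
    for costed in costed_lines:
        if costed.cost_method not in qualifying:
            continue
        if costed.line.charge == 0:
            continue
        total_cost += costed.cost_nominal
        total_charge += costed.line.charge
        insts.add(costed.line.institution_id)
        years.add(costed.line.service_year)
    if total_charge == 0:
        raise ReferenceBuildError("no qualifying (non-zero-charge, fee-costed) lines")
    return ImputationRate(
        institution_id=institution_id or (insts.pop() if len(insts) == 1 else "POOLED"),
        year=year or (years.pop() if len(years) == 1 else 0),
        rate=total_cost / total_charge,
    )


# ---------------------------------------------------------------------------
# cost reports, crosswalk, and CCR tables


@dataclass(frozen=True)
class CostCenterRow:
    cost_center_name: str
    total_cost: Decimal
    total_charge: Decimal

    def __post_init__(self) -> None:
        if self.total_cost < 0:
            raise ValueError("cost-center cost must be non-negative")


@dataclass(frozen=True)
class CostCenterReport:
    """One hospital's annual cost report: costs and charges by cost center."""

    hospital_id: str
    report_year: int
    rows: tuple[CostCenterRow, ...]


@dataclass(frozen=True)
class CrosswalkEntry:
    """Inclusive UB-revenue-code range mapped to one cost-report cost center."""

    low: str
    high: str
    cost_center_name: str

    def __post_init__(self) -> None:
        if len(self.low) != 4 or len(self.high) != 4:
            raise ValueError("revenue codes are 4-character zero-padded strings")
        if self.low > self.high:
            raise ValueError(f"range {self.low}-{self.high} inverted")

    def contains(self, code: str) -> bool:
        return self.low <= code <= self.high


def validate_crosswalk(entries: Sequence[CrosswalkEntry]) -> None:
    ordered = sorted(entries, key=lambda e: e.low)
    for a, b in zip(ordered, ordered[1:]):
        if b.low <= a.high:
            raise ReferenceBuildError(
                f"overlapping crosswalk ranges {a.low}-{a.high} and {b.low}-{b.high}"
            )


def crosswalk_cost_center(entries: Sequence[CrosswalkEntry], code: str) -> str | None:
    for entry in entries:
        if entry.contains(code):
            return entry.cost_center_name
    return None


class CCRProvenance(str, Enum):
    MAPPED = "mapped"
    HOSPITAL_AVERAGE = "hospital_average"
    PRIOR_YEAR = "prior_year"


@dataclass(frozen=True)
class CCRTable:
    """Per-institution (year, UB revenue code) → cost-to-charge ratio."""

    institution_id: str
    entries: Mapping[tuple[int, str], Decimal]
    hospital_average: Mapping[int, Decimal]

    def __post_init__(self) -> None:
        for key, ratio in self.entries.items():
            if ratio <= 0:
                raise ValueError(f"CCR for {key} must be positive")
        for year in {y for y, _ in self.entries}:
            if year not in self.hospital_average:
                raise ValueError(f"year {year} has entries but no hospital average")

    @property
    def years(self) -> set[int]:
        return set(self.hospital_average)


def _enumerate_codes(entry: CrosswalkEntry) -> list[str]:
    lo, hi = int(entry.low), int(entry.high)
    return [f"{c:04d}" for c in range(lo, hi + 1)]


def compute_ccr_table(
    institution_id: str,
    reports: Sequence[CostCenterReport],
    crosswalk: Sequence[CrosswalkEntry],
    window: int = 3,
    combine_hospitals: bool = True,
) -> CCRTable:
    """Build moving-average cost-center CCRs from cost reports.

    The ratio for (year y, revenue code r) pools the costs and charges of r's
    cost center over report years {y-window+1 … y} — Σcosts / Σcharges, not a
    mean of yearly ratios — combining hospitals when ``combine_hospitals``.
    The window truncates to available years at the start of the series.  The
    hospital-average ratio for a year pools all cost centers the same way.
    Revenue codes whose cost center never appears map to nothing (the lookup
    falls back to the hospital average).
    """
    if not reports:
        raise ReferenceBuildError("no cost reports supplied")
    validate_crosswalk(crosswalk)
    if not combine_hospitals and len({r.hospital_id for r in reports}) > 1:
        raise ReferenceBuildError(
            "multiple hospitals supplied with combine_hospitals=False; "
            "build one table per hospital"
        )
    years = sorted({r.report_year for r in reports})
    entries: dict[tuple[int, str], Decimal] = {}
    averages: dict[int, Decimal] = {}
    for year in years:
        pool = [r for r in reports if year - window < r.report_year <= year]
        center_cost: dict[str, Decimal] = {}
        center_charge: dict[str, Decimal] = {}
        for report in pool:
            for row in report.rows:
                center_cost[row.cost_center_name] = (
                    center_cost.get(row.cost_center_name, Decimal(0)) + row.total_cost
                )
                center_charge[row.cost_center_name] = (
                    center_charge.get(row.cost_center_name, Decimal(0)) + row.total_charge
                )
        total_cost = sum(center_cost.values(), Decimal(0))
        total_charge = sum(center_charge.values(), Decimal(0))
        if total_charge == 0:
            raise ReferenceBuildError(f"zero pooled hospital charge in {year}")
        averages[year] = total_cost / total_charge
        for xw in crosswalk:
            if xw.cost_center_name not in center_cost:
                continue
            charge = center_charge[xw.cost_center_name]
            if charge == 0:
                raise ReferenceBuildError(
                    f"zero pooled charge for cost center {xw.cost_center_name!r} in {year}"
                )
            ratio = center_cost[xw.cost_center_name] / charge
            for code in _enumerate_codes(xw):
                entries[(year, code)] = ratio
    return CCRTable(institution_id=institution_id, entries=entries, hospital_average=averages)


def lookup_ccr(
    table: CCRTable, ub_revenue_code: str | None, year: int
) -> tuple[Decimal, CCRProvenance]:
    """Resolve a cost-to-charge ratio with fallbacks.

    Exact (year, code) hit → ``mapped``; unmapped code → the year's hospital
    average; a service year past the last available report carries the most
    recent report year's ratios forward with provenance ``prior_year``
    (cost-report availability lags about a year).
    """
    if not table.hospital_average:
        raise ReferenceLookupError(f"CCR table for {table.institution_id} is empty")
    last_year = max(table.hospital_average)
    first_year = min(table.hospital_average)
    if year < first_year:
        raise ReferenceLookupError(
            f"service year {year} precedes first cost-report year {first_year}"
        )
    effective_year = min(year, last_year)
    carried = effective_year != year
    if ub_revenue_code is not None and (effective_year, ub_revenue_code) in table.entries:
        ratio = table.entries[(effective_year, ub_revenue_code)]
        return ratio, CCRProvenance.PRIOR_YEAR if carried else CCRProvenance.MAPPED
    ratio = table.hospital_average[effective_year]
    return ratio, CCRProvenance.PRIOR_YEAR if carried else CCRProvenance.HOSPITAL_AVERAGE


# ---------------------------------------------------------------------------
# inflation


@dataclass(frozen=True)
class InflationIndexTable:
    """GDP implicit-price-deflator based inflation indexes.

    index(service_year, target_year) = deflator(target) / deflator(service),
    so index(y, y) = 1 and the index is multiplicative across years.
    """

    gdp_deflator_by_year: Mapping[int, Decimal]

    def __post_init__(self) -> None:
        for year, deflator in self.gdp_deflator_by_year.items():
            if deflator <= 0:
                raise ValueError(f"deflator for {year} must be positive")

    @property
    def years(self) -> set[int]:
        return set(self.gdp_deflator_by_year)

    def index(self, service_year: int, target_year: int) -> Decimal:
        for year in (service_year, target_year):
            if year not in self.gdp_deflator_by_year:
                raise ReferenceLookupError(f"no GDP deflator for year {year}")
        return (
            self.gdp_deflator_by_year[target_year] / self.gdp_deflator_by_year[service_year]
        )


def inflation_index(table: InflationIndexTable, service_year: int, target_year: int) -> Decimal:
    return table.index(service_year, target_year)


# ---------------------------------------------------------------------------
# the versioned reference bundle


@dataclass
class ReferenceBundle:
    """All reference tables versioned together for reproducible cohort runs."""

    fee_schedule: FeeScheduleTable
    modifier_rules: list[ModifierRule]
    anesthesia: AnesthesiaParams
    imputation_rates: dict[tuple[str, int], Decimal]
    ccr_by_institution: dict[str, CCRTable]
    inflation: InflationIndexTable
    anesthesia_code_range: tuple[str, str] = ("00100", "01999")

    def is_anesthesia_code(self, code: str | None) -> bool:
        if code is None:
            return False
        lo, hi = self.anesthesia_code_range
        return lo <= code <= hi

    def imputation_rate(self, institution_id: str, year: int) -> Decimal | None:
        return self.imputation_rates.get((institution_id, year))

    # -- persistence ------------------------------------------------------

    FILES = (
        "fee_schedule.csv",
        "modifier_rules.csv",
        "anesthesia_base_units.csv",
        "anesthesia_conversion_factors.csv",
        "anesthesia_billing_cf.csv",
        "imputation_rates.csv",
        "ccr.csv",
        "ccr_hospital_average.csv",
        "gdp_deflators.csv",
        "inflation_index.csv",
        "bundle_config.json",
    )

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)

        def write(name: str, header: list[str], rows: Iterable[Sequence[object]]):
            with (directory / name).open("w", newline="", encoding="utf-8") as fh:
                w = csv.writer(fh)
                w.writerow(header)
                for row in rows:
                    w.writerow([str(v) for v in row])

        write(
            "fee_schedule.csv",
            ["year", "code", "modifier", "nonfacility_fee", "facility_fee", "source_schedule"],
            (
                (e.year, e.code, e.modifier, e.nonfacility_fee, e.facility_fee, e.source_schedule.value)
                for e in self.fee_schedule.sorted_entries()
            ),
        )
        write(
            "modifier_rules.csv",
            ["modifier", "service_type", "rule_kind", "value"],
            (
                (r.modifier, r.service_type.value, r.rule_kind.value, r.value)
                for r in self.modifier_rules
            ),
        )
        write(
            "anesthesia_base_units.csv",
            ["code", "base_units"],
            sorted(self.anesthesia.base_units_by_code.items()),
        )
        write(
            "anesthesia_conversion_factors.csv",
            ["year", "conversion_factor"],
            sorted(self.anesthesia.conversion_factor_by_year.items()),
        )
        write(
            "anesthesia_billing_cf.csv",
            ["institution_id", "year", "billing_conversion_factor"],
            sorted(
                (inst, year, cf)
                for (inst, year), cf in self.anesthesia.billing_cf_by_institution_year.items()
            ),
        )
        write(
            "imputation_rates.csv",
            ["institution_id", "year", "rate"],
            sorted((inst, year, rate) for (inst, year), rate in self.imputation_rates.items()),
        )
        write(
            "ccr.csv",
            ["institution_id", "year", "ub_revenue_code", "ratio"],
            sorted(
                (inst, year, code, ratio)
                for inst, table in self.ccr_by_institution.items()
                for (year, code), ratio in table.entries.items()
            ),
        )
        write(
            "ccr_hospital_average.csv",
            ["institution_id", "year", "ratio"],
            sorted(
                (inst, year, ratio)
                for inst, table in self.ccr_by_institution.items()
                for year, ratio in table.hospital_average.items()
            ),
        )
        write(
            "gdp_deflators.csv",
            ["year", "deflator"],
            sorted(self.inflation.gdp_deflator_by_year.items()),
        )
        # derived all-pairs index file, (service_year, target_year, index)
        years = sorted(self.inflation.years)
        write(
            "inflation_index.csv",
            ["service_year", "target_year", "index"],
            ((s, t, self.inflation.index(s, t)) for s in years for t in years),
        )
        (directory / "bundle_config.json").write_text(
            json.dumps(
                {
                    "anesthesia_code_range": list(self.anesthesia_code_range),
                    "institutions": sorted(self.ccr_by_institution),
                    "fee_years": sorted(self.fee_schedule.years),
                    "deflator_years": sorted(self.inflation.years),
                },
                indent=2,
            )
            + "\n"
        )
        self._write_manifest(directory)

    def _write_manifest(self, directory: Path) -> None:
        checksums = {}
        for name in self.FILES:
            path = directory / name
            if path.exists():
                checksums[name] = hashlib.sha256(path.read_bytes()).hexdigest()
        bundle_hash = hashlib.sha256(
            json.dumps(checksums, sort_keys=True).encode()
        ).hexdigest()
        (directory / "manifest.json").write_text(
            json.dumps({"files": checksums, "bundle_hash": bundle_hash}, indent=2) + "\n"
        )

    @property
    def manifest_hash(self) -> str:
        """Content hash over all reference tables (provenance stamp for outputs)."""
        h = hashlib.sha256()
        for e in self.fee_schedule.sorted_entries():
            h.update(repr((e.year, e.code, e.modifier, str(e.nonfacility_fee),
                           str(e.facility_fee), e.source_schedule.value)).encode())
        for r in self.modifier_rules:
            h.update(repr((r.modifier, r.service_type.value, r.rule_kind.value, str(r.value))).encode())
        for key in sorted(self.anesthesia.base_units_by_code):
            h.update(repr((key, str(self.anesthesia.base_units_by_code[key]))).encode())
        for key in sorted(self.imputation_rates):
            h.update(repr((key, str(self.imputation_rates[key]))).encode())
        for inst in sorted(self.ccr_by_institution):
            table = self.ccr_by_institution[inst]
            for key in sorted(table.entries):
                h.update(repr((inst, key, str(table.entries[key]))).encode())
        for year in sorted(self.inflation.years):
            h.update(repr((year, str(self.inflation.gdp_deflator_by_year[year]))).encode())
        return h.hexdigest()

    @classmethod
    def load(cls, directory: str | Path) -> "ReferenceBundle":
        directory = Path(directory)

        def read(name: str) -> list[dict[str, str]]:
            with (directory / name).open(newline="", encoding="utf-8") as fh:
                return list(csv.DictReader(fh))

        fee_entries = [
            FeeScheduleEntry(
                year=int(r["year"]),
                code=r["code"],
                modifier=r["modifier"],
                nonfacility_fee=Decimal(r["nonfacility_fee"]),
                facility_fee=Decimal(r["facility_fee"]),
                source_schedule=SourceSchedule(r["source_schedule"]),
            )
            for r in read("fee_schedule.csv")
        ]
        rules = [
            ModifierRule(
                modifier=r["modifier"],
                service_type=ModifierService(r["service_type"]),
                rule_kind=RuleKind(r["rule_kind"]),
                value=Decimal(r["value"]),
            )
            for r in read("modifier_rules.csv")
        ]
        anesthesia = AnesthesiaParams(
            base_units_by_code={r["code"]: Decimal(r["base_units"]) for r in read("anesthesia_base_units.csv")},
            conversion_factor_by_year={
                int(r["year"]): Decimal(r["conversion_factor"])
                for r in read("anesthesia_conversion_factors.csv")
            },
            billing_cf_by_institution_year={
                (r["institution_id"], int(r["year"])): Decimal(r["billing_conversion_factor"])
                for r in read("anesthesia_billing_cf.csv")
            },
        )
        rates = {
            (r["institution_id"], int(r["year"])): Decimal(r["rate"])
            for r in read("imputation_rates.csv")
        }
        ccr_entries: dict[str, dict[tuple[int, str], Decimal]] = {}
        for r in read("ccr.csv"):
            ccr_entries.setdefault(r["institution_id"], {})[
                (int(r["year"]), r["ub_revenue_code"])
            ] = Decimal(r["ratio"])
        ccr_avg: dict[str, dict[int, Decimal]] = {}
        for r in read("ccr_hospital_average.csv"):
            ccr_avg.setdefault(r["institution_id"], {})[int(r["year"])] = Decimal(r["ratio"])
        ccr_tables = {
            inst: CCRTable(
                institution_id=inst,
                entries=ccr_entries.get(inst, {}),
                hospital_average=avg,
            )
            for inst, avg in ccr_avg.items()
        }
        inflation = InflationIndexTable(
            gdp_deflator_by_year={int(r["year"]): Decimal(r["deflator"]) for r in read("gdp_deflators.csv")}
        )
        config = json.loads((directory / "bundle_config.json").read_text())
        return cls(
            fee_schedule=FeeScheduleTable(fee_entries),
            modifier_rules=rules,
            anesthesia=anesthesia,
            imputation_rates=rates,
            ccr_by_institution=ccr_tables,
            inflation=inflation,
            anesthesia_code_range=tuple(config["anesthesia_code_range"]),
        )
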