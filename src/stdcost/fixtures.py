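"""Synthetic reference bundles and billing extracts with known-answer ledgers.

Every service line is constructed *backwards* from a chosen cost method, so
its true standardized cost is known at generation time: a fee-schedule line
bills a code priced in the stacked schedule and carries a charge of fee ×
markup; an imputed line uses a code absent from every schedule; an anesthesia
line carries minutes, an ASA status modifier, and possibly a medical-direction
modifier; a hospital line bills a revenue code with a known cost-center CCR
(or a deliberately unmapped one to exercise the hospital-average fallback).
The accompanying ledger records each line's expected method and nominal cost
to the cent, which makes end-to-end engine checks exact rather than
statistical.

All draws flow through one seeded ``random.Random`` instance per artifact;
identical (seed, spec) gives byte-identical output.  Patient identifiers and
codes are synthetic tokens.
"""

from __future__ import annotations

import csv
import datetime as dt
import random
from dataclasses import dataclass
from decimal import Decimal
from pathlib import Path
from typing import Mapping, Sequence

from ._money import D, round_cents, round_tenth
from .billing_model import (
    ClaimForm,
    CostMethod,
    DialectConfig,
    EpisodeRecord,
    PlaceOfService,
    ServiceLine,
    write_billing_extract,
    write_episodes,
)
from .errors import GenerationError
from .reference_data import (
    AnesthesiaParams,
    CostCenterReport,
    CostCenterRow,
    CrosswalkEntry,
    FeeScheduleTable,
    InflationIndexTable,
    ReferenceBundle,
    SourceSchedule,
    build_stacked_fee_schedule,
    canonical_modifier_rules,
    compute_ccr_table,
)

#: dialect for reading fixture extracts (flags HDR* charge-master codes as header lines)
FIXTURE_DIALECT = DialectConfig(name="fixture", header_charge_master_prefix="HDR")

#: sample UB-revenue-code → cost-center crosswalk (standard cost-report centers)
SAMPLE_CROSSWALK: tuple[tuple[str, str, str], ...] = (
    ("0115", "0122", "Adults and Pediatrics (General Routine Care)"),
    ("0171", "0173", "Nursery"),
    ("0200", "0200", "Intensive Care Unit"),
    ("0250", "0258", "Drugs Charged to Patients"),
    ("0260", "0264", "Drugs Charged to Patients"),
    ("0270", "0279", "Medical Supplies Charged to Patients"),
    ("0290", "0299", "Medical Supplies Charged to Patients"),
    ("0300", "0319", "Laboratory"),
    ("0320", "0324", "Radiology-Diagnostic"),
    ("0340", "0343", "Radiology-Diagnostic"),
    ("0350", "0359", "Computed Tomography (CT) Scan"),
    ("0360", "0360", "Operating Room"),
    ("0370", "0370", "Anesthesiology"),
    ("0390", "0391", "Blood"),
    ("0401", "0403", "Radiology-Diagnostic"),
    ("0410", "0413", "Respiratory Therapy"),
    ("0420", "0429", "Physical Therapy"),
)

#: revenue codes deliberately absent from the crosswalk (hospital-average fallback)
UNMAPPED_REVENUE_CODES = ("0940", "0960", "0972")

INSTITUTIONS: Mapping[str, tuple[str, ...]] = {
    "INST-A": ("A-H1", "A-H2"),  # two hospitals combined into one CCR table
    "INST-B": ("B-H1",),
}

#: within-stratum method fractions emulating a large mixed professional/hospital
#: billing population (professional ≈ 48.6% of lines)
_DEFAULT_PROF_SHARE = 0.486
_DEFAULT_PROF_METHODS = {
    "PFS": 0.328,
    "laboratory": 0.280,
    "drug": 0.017,
    "DME": 0.001,
    "gap": 0.045,
    "header": 0.033,
    "impute": 0.007,
}
_DEFAULT_ANESTHESIA_FRAC = 0.008   # of professional lines
_DEFAULT_ZERO_CHARGE_FRAC = 0.281  # of professional lines; hospital uses 0.266
_DEFAULT_HOSP_ZERO_FRAC = 0.266


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic warehouse fixture."""

    seed: int
    years: tuple[int, int] = (2010, 2014)  # inclusive service-year range
    n_patients: int = 50
    n_lines: int = 1000
    method_mix: Mapping[str, float] | None = None  # overrides the default mix
    negative_line_rate: float = 0.02   # billing corrections (negative charge+quantity)
    zero_charge_rate: float | None = None   # overrides the zero-charge mass in both strata
    anesthesia_rate: float | None = None    # overrides the anesthesia mass (professional)
    nonfinal_rate: float = 0.05        # lines that are not the final claim submission
    unmapped_revenue_rate: float = 0.05  # CCR lines planted with an unmapped revenue code
    charge_markup: tuple[float, float] = (1.2, 3.0)  # charge = fee x Uniform markup

    def __post_init__(self) -> None:
        lo, hi = self.years
        if lo > hi:
            raise ValueError("empty year range")
        for rate in (self.negative_line_rate, self.nonfinal_rate, self.unmapped_revenue_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        total = sum(self.effective_mix().values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"method mix sums to {total}, not 1")

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    def effective_mix(self) -> dict[str, float]:
        """Per-line method distribution over stratified method keys.

        Keys: the professional fee methods, ``anesthesia``, ``impute``,
        ``header``, ``zero_charge_professional``, ``CCR``, and
        ``zero_charge_hospital``.
        """
        if self.method_mix is not None:
            return dict(self.method_mix)
        prof = _DEFAULT_PROF_SHARE
        hosp = 1.0 - prof
        zc = self.zero_charge_rate
        prof_zero = zc if zc is not None else _DEFAULT_ZERO_CHARGE_FRAC
        hosp_zero = zc if zc is not None else _DEFAULT_HOSP_ZERO_FRAC
        anes = self.anesthesia_rate if self.anesthesia_rate is not None else _DEFAULT_ANESTHESIA_FRAC
        rest = 1.0 - prof_zero - anes
        if rest < 0:
            raise ValueError("zero_charge_rate + anesthesia_rate exceed 1")
        base_total = sum(_DEFAULT_PROF_METHODS.values())
        mix = {
            key: prof * rest * frac / base_total for key, frac in _DEFAULT_PROF_METHODS.items()
        }
        mix["anesthesia"] = prof * anes
        mix["zero_charge_professional"] = prof * prof_zero
        mix["CCR"] = hosp * (1.0 - hosp_zero)
        mix["zero_charge_hospital"] = hosp * hosp_zero
        return mix


@dataclass(frozen=True)
class LedgerEntry:
    """Expected outcome for one generated line."""

    line_id: str
    stratum: str  # professional | hospital
    expected_method: CostMethod
    expected_cost_nominal: Decimal
    final_billed: bool


# ---------------------------------------------------------------------------
# reference bundle generation


def _drifted_fee(rng: random.Random, base_cents: int, year: int, year0: int) -> Decimal:
    # mild year-on-year fee drift, re-rounded to cents
    drift = D(1) + D(year - year0) * D("0.015")
    return round_cents(D(base_cents) / 100 * drift)


def generate_reference_bundle(spec: FixtureSpec) -> ReferenceBundle:
    """Generate a complete, self-consistent reference bundle for ``spec.years``."""
    rng = random.Random(f"{spec.seed}-bundle")
    years = spec.year_list
    year0 = years[0]

    pfs_codes = [f"{20000 + 7 * i:05d}" for i in range(30)]
    lab_codes = [f"{80000 + 11 * i:05d}" for i in range(25)]
    dme_codes = [f"E{100 + 13 * i:04d}" for i in range(8)]
    pen_codes = [f"B{4000 + 9 * i:04d}" for i in range(4)]
    drug_codes = [f"J{1000 + 10 * i:04d}" for i in range(10)]
    gap_codes = [f"{30000 + 13 * i:05d}" for i in range(15)]

    base_cents = {
        code: rng.randint(800, 45000)
        for code in pfs_codes + lab_codes + dme_codes + pen_codes + drug_codes + gap_codes
    }

    def single_fee_rows(codes: list[str]) -> list[dict]:
        return [
            {"year": y, "code": c, "fee": _drifted_fee(rng, base_cents[c], y, year0)}
            for y in years
            for c in codes
        ]

    pfs_rows: list[dict] = []
    for y in years:
        for i, code in enumerate(pfs_codes):
            nonfac = _drifted_fee(rng, base_cents[code], y, year0)
            fac = round_cents(nonfac * D("0.7"))  # facility practice expense is lower
            pfs_rows.append(
                {"year": y, "code": code, "nonfacility_fee": nonfac, "facility_fee": fac}
            )
            if i % 3 == 0:  # professional/technical component rows for some codes
                for modifier, frac in (("26", D("0.6")), ("TC", D("0.4"))):
                    pfs_rows.append(
                        {
                            "year": y,
                            "code": code,
                            "modifier": modifier,
                            "nonfacility_fee": round_cents(nonfac * frac),
                            "facility_fee": round_cents(fac * frac),
                        }
                    )
    gap_rows: list[dict] = []
    for y in years:
        for i, code in enumerate(gap_codes):
            fee = _drifted_fee(rng, base_cents[code], y, year0)
            if i % 2 == 0:
                gap_rows.append(
                    {
                        "year": y,
                        "code": code,
                        "nonfacility_fee": fee,
                        "facility_fee": round_cents(fee * D("0.8")),
                    }
                )
            else:
                gap_rows.append({"year": y, "code": code, "fee": fee})

    fee_schedule = build_stacked_fee_schedule(
        [
            (SourceSchedule.PFS, pfs_rows),
            (SourceSchedule.LABORATORY, single_fee_rows(lab_codes)),
            (SourceSchedule.DME, single_fee_rows(dme_codes)),
            (SourceSchedule.PEN, single_fee_rows(pen_codes)),
            (SourceSchedule.DRUG, single_fee_rows(drug_codes)),
            (SourceSchedule.GAP, gap_rows),
        ]
    )

    anesthesia_codes = [f"{100 + 50 * i:05d}" for i in range(10)]  # 00100 … 00550
    anesthesia = AnesthesiaParams(
        base_units_by_code={c: D(rng.randint(3, 12)) for c in anesthesia_codes},
        conversion_factor_by_year={y: D(rng.randint(1800, 2400)) / 100 for y in years},
        billing_cf_by_institution_year={
            (inst, y): D(rng.randint(4000, 6500)) / 100 for inst in INSTITUTIONS for y in years
        },
    )

    imputation_rates = {
        (inst, y): D(rng.randint(3500, 9000)) / 10000 for inst in INSTITUTIONS for y in years
    }

    crosswalk = [CrosswalkEntry(lo, hi, center) for lo, hi, center in SAMPLE_CROSSWALK]
    centers = sorted({center for _, _, center in SAMPLE_CROSSWALK})
    ccr_by_institution = {}
    for inst, hospitals in INSTITUTIONS.items():
        reports = []
        for hospital in hospitals:
            for y in years:
                rows = []
                for center in centers:
                    charge_cents = rng.randint(10_000_00, 90_000_000_00)
                    ratio = rng.randint(20, 90) / 100
                    cost_cents = int(charge_cents * ratio)
                    rows.append(
                        CostCenterRow(
                            cost_center_name=center,
                            total_cost=D(cost_cents) / 100,
                            total_charge=D(charge_cents) / 100,
                        )
                    )
                reports.append(
                    CostCenterReport(hospital_id=hospital, report_year=y, rows=tuple(rows))
                )
        ccr_by_institution[inst] = compute_ccr_table(
            inst, reports, crosswalk, window=3, combine_hospitals=True
        )

    deflator = D("90.000")
    deflators = {}
    for y in range(years[0], years[-1] + 2):  # one year past the range for target years
        deflators[y] = deflator
        deflator = (deflator * D("1.021")).quantize(D("0.001"))

    return ReferenceBundle(
        fee_schedule=fee_schedule,
        modifier_rules=canonical_modifier_rules(),
        anesthesia=anesthesia,
        imputation_rates=imputation_rates,
        ccr_by_institution=ccr_by_institution,
        inflation=InflationIndexTable(gdp_deflator_by_year=deflators),
        anesthesia_code_range=("00100", "01999"),
    )


# ---------------------------------------------------------------------------
# billing extract generation


_FEE_SOURCES = {
    "PFS": SourceSchedule.PFS,
    "laboratory": SourceSchedule.LABORATORY,
    "DME": SourceSchedule.DME,
    "drug": SourceSchedule.DRUG,
    "gap": SourceSchedule.GAP,
}

_PERCENT_MODIFIERS = ("50", "51", "62", "AS", "80", "81", "82")
_DIRECTION_MODIFIERS = ("QK", "QX", "QY")
_STATUS_UNITS = {"P1": 0, "P2": 0, "P3": 1, "P4": 2, "P5": 3, "P6": 0}
_PERCENTS = {"50": D("1.5"), "51": D("0.5"), "62": D("0.625"),
             "AS": D("0.16"), "80": D("0.16"), "81": D("0.16"), "82": D("0.16")}


def _source_codes(table: FeeScheduleTable, source: SourceSchedule) -> list[str]:
    return sorted({e.code for e in table.sorted_entries() if e.source_schedule is source})


def _rand_date(rng: random.Random, year: int) -> dt.date:
    start = dt.date(year, 1, 1).toordinal()
    end = dt.date(year, 12, 31).toordinal()
    return dt.date.fromordinal(rng.randint(start, end))


def generate_billing_extract(
    spec: FixtureSpec, refs: ReferenceBundle
) -> tuple[list[ServiceLine], list[LedgerEntry]]:
    """Generate ``spec.n_lines`` service lines plus the expected-cost ledger."""
    if not set(spec.year_list) <= refs.inflation.years:
        raise GenerationError("reference bundle does not cover the requested years")
    if not refs.anesthesia.base_units_by_code and spec.effective_mix().get("anesthesia", 0) > 0:
        raise GenerationError("anesthesia lines requested but no anesthesia base units in refs")

    rng = random.Random(f"{spec.seed}-extract")
    institutions = sorted(INSTITUTIONS)
    patients = [(f"PT{i:05d}", institutions[i % len(institutions)]) for i in range(spec.n_patients)]
    mix = spec.effective_mix()
    mix_keys = sorted(mix)
    weights = [mix[k] for k in mix_keys]
    codes_by_source = {name: _source_codes(refs.fee_schedule, src) for name, src in _FEE_SOURCES.items()}
    pen_codes = _source_codes(refs.fee_schedule, SourceSchedule.PEN)
    anesthesia_codes = sorted(refs.anesthesia.base_units_by_code)
    mapped_codes_by_inst_year: dict[tuple[str, int], list[str]] = {}
    for inst, table in refs.ccr_by_institution.items():
        for (year, code) in table.entries:
            mapped_codes_by_inst_year.setdefault((inst, year), []).append(code)
    for key in mapped_codes_by_inst_year:
        mapped_codes_by_inst_year[key].sort()

    lines: list[ServiceLine] = []
    ledger: list[LedgerEntry] = []

    for i in range(spec.n_lines):
        line_id = f"L{i:06d}"
        patient_id, inst = patients[rng.randrange(len(patients))]
        year = rng.choice(spec.year_list)
        date = _rand_date(rng, year)
        kind = rng.choices(mix_keys, weights=weights, k=1)[0]
        negative = rng.random() < spec.negative_line_rate
        final = rng.random() >= spec.nonfinal_rate
        markup = D(rng.randint(int(spec.charge_markup[0] * 100), int(spec.charge_markup[1] * 100))) / 100

        common = dict(
            line_id=line_id,
            patient_id=patient_id,
            institution_id=inst,
            service_date=date,
            final_billed=final,
        )

        if kind in _FEE_SOURCES:
            source = _FEE_SOURCES[kind]
            pool = codes_by_source[kind]
            if kind == "DME" and pen_codes and rng.random() < 0.3:
                source, pool = SourceSchedule.PEN, pen_codes  # PEN lines carry the DME label
            code = rng.choice(pool)
            place = rng.choice((PlaceOfService.FACILITY, PlaceOfService.NONFACILITY))
            modifiers: list[str] = []
            if source is SourceSchedule.PFS and rng.random() < 0.15:
                selecting = rng.choice(("26", "TC"))
                if refs.fee_schedule.get(year, code, selecting, source) is not None:
                    modifiers.append(selecting)
            if rng.random() < 0.3:
                modifiers.append(rng.choice(_PERCENT_MODIFIERS))
            entry = refs.fee_schedule.get(
                year, code, modifiers[0] if modifiers and modifiers[0] in ("26", "TC") else "", source
            )
            fee = entry.facility_fee if place is PlaceOfService.FACILITY else entry.nonfacility_fee
            quantity = rng.randint(1, 3)
            expected = fee * quantity
            for m in modifiers:
                if m in _PERCENTS:
                    expected *= _PERCENTS[m]
            expected = round_cents(expected)
            charge = round_cents(fee * quantity * markup)
            if negative:
                quantity, charge, expected = -quantity, -charge, -expected
            lines.append(
                ServiceLine(
                    **common,
                    charge_master_code=f"CM{rng.randint(10000, 99999)}",
                    procedure_code=code,
                    modifiers=tuple(modifiers),
                    place_of_service=place,
                    quantity=quantity,
                    charge=charge,
                    claim_form=ClaimForm.PROFESSIONAL,
                )
            )
            method = CostMethod.DME if source is SourceSchedule.PEN else CostMethod(kind)
            ledger.append(LedgerEntry(line_id, "professional", method, expected, final))

        elif kind == "anesthesia":
            code = rng.choice(anesthesia_codes)
            cf = refs.anesthesia.conversion_factor_by_year[year]
            quantity = 1
            if rng.random() < 0.7:  # unit-based route: minutes recorded in the DSS
                minutes = D(rng.randint(10, 240))
                modifiers = []
                status = None
                if rng.random() < 0.6:
                    status = rng.choice(sorted(_STATUS_UNITS))
                    modifiers.append(status)
                direction = rng.random() < 0.3
                if direction:
                    modifiers.append(rng.choice(_DIRECTION_MODIFIERS))
                units = (
                    refs.anesthesia.base_units_by_code[code]
                    + round_tenth(minutes / 15)
                    + D(_STATUS_UNITS.get(status or "", 0))
                )
                expected = units * cf
                if direction:
                    expected *= D("0.5")
                expected = round_cents(expected)
                charge = round_cents(expected * markup)
                anesthesia_minutes = minutes
            else:  # charge-conversion route: units priced at the billing CF
                billing_cf = refs.anesthesia.billing_cf_by_institution_year[(inst, year)]
                billed_units = D(rng.randint(40, 200)) / 10
                charge = round_cents(billed_units * billing_cf)
                expected = round_cents(charge / billing_cf * cf)
                modifiers = []
                anesthesia_minutes = None
            if negative:
                quantity, charge, expected = -quantity, -charge, -expected
            lines.append(
                ServiceLine(
                    **common,
                    charge_master_code=f"CM{rng.randint(10000, 99999)}",
                    procedure_code=code,
                    modifiers=tuple(modifiers),
                    place_of_service=PlaceOfService.FACILITY,
                    quantity=quantity,
                    charge=charge,
                    claim_form=ClaimForm.PROFESSIONAL,
                    anesthesia_minutes=anesthesia_minutes,
                )
            )
            ledger.append(LedgerEntry(line_id, "professional", CostMethod.ANESTHESIA, expected, final))

        elif kind == "impute":
            code = f"X9{rng.randint(100, 999)}"  # absent from every schedule
            rate = refs.imputation_rates[(inst, year)]
            charge = D(rng.randint(500, 80000)) / 100
            expected = round_cents(charge * rate)
            quantity = 1
            if negative:
                quantity, charge, expected = -quantity, -charge, -expected
            lines.append(
                ServiceLine(
                    **common,
                    charge_master_code=f"CM{rng.randint(10000, 99999)}",
                    procedure_code=code,
                    modifiers=(),
                    place_of_service=PlaceOfService.NONFACILITY,
                    quantity=quantity,
                    charge=charge,
                    claim_form=ClaimForm.PROFESSIONAL,
                )
            )
            ledger.append(LedgerEntry(line_id, "professional", CostMethod.IMPUTE, expected, final))

        elif kind == "header":
            charge = D(rng.randint(0, 40000)) / 100
            lines.append(
                ServiceLine(
                    **common,
                    charge_master_code=f"HDR{rng.randint(1000, 9999)}",
                    procedure_code=rng.choice(codes_by_source["PFS"]),
                    modifiers=(),
                    place_of_service=PlaceOfService.NONFACILITY,
                    quantity=1,
                    charge=charge,
                    claim_form=ClaimForm.PROFESSIONAL,
                    header=True,
                )
            )
            ledger.append(LedgerEntry(line_id, "professional", CostMethod.HEADER, D("0.00"), final))

        elif kind == "zero_charge_professional":
            lines.append(
                ServiceLine(
                    **common,
                    charge_master_code=f"CM{rng.randint(10000, 99999)}",
                    procedure_code=rng.choice(codes_by_source["PFS"] + [f"X9{rng.randint(100, 999)}"]),
                    modifiers=(),
                    place_of_service=PlaceOfService.NONFACILITY,
                    quantity=1,
                    charge=D("0.00"),
                    claim_form=ClaimForm.PROFESSIONAL,
                )
            )
            ledger.append(LedgerEntry(line_id, "professional", CostMethod.ZERO_CHARGE, D("0.00"), final))

        elif kind == "CCR":
            table = refs.ccr_by_institution[inst]
            unmapped = rng.random() < spec.unmapped_revenue_rate
            if unmapped:
                revenue_code = rng.choice(UNMAPPED_REVENUE_CODES)
                ratio = table.hospital_average[year]
            else:
                revenue_code = rng.choice(mapped_codes_by_inst_year[(inst, year)])
                ratio = table.entries[(year, revenue_code)]
            charge = D(rng.randint(1000, 500000)) / 100
            quantity = 1
            if negative:
                quantity, charge = -quantity, -charge
            expected = round_cents(charge * ratio)
            lines.append(
                ServiceLine(
                    **common,
                    charge_master_code=f"CM{rng.randint(10000, 99999)}",
                    procedure_code=None,
                    modifiers=(),
                    place_of_service=PlaceOfService.FACILITY,
                    quantity=quantity,
                    charge=charge,
                    ub_revenue_code=revenue_code,
                    claim_form=ClaimForm.HOSPITAL,
                )
            )
            ledger.append(LedgerEntry(line_id, "hospital", CostMethod.CCR, expected, final))

        elif kind == "zero_charge_hospital":
            revenue_code = rng.choice(mapped_codes_by_inst_year[(inst, year)])
            lines.append(
                ServiceLine(
                    **common,
                    charge_master_code=f"CM{rng.randint(10000, 99999)}",
                    procedure_code=None,
                    modifiers=(),
                    place_of_service=PlaceOfService.FACILITY,
                    quantity=1,
                    charge=D("0.00"),
                    ub_revenue_code=revenue_code,
                    claim_form=ClaimForm.HOSPITAL,
                )
            )
            ledger.append(LedgerEntry(line_id, "hospital", CostMethod.ZERO_CHARGE, D("0.00"), final))

        else:  # pragma: no cover - guarded by FixtureSpec validation
            raise GenerationError(f"unknown method-mix key {kind!r}")

    return lines, ledger


def generate_episodes(spec: FixtureSpec) -> list[EpisodeRecord]:
    """A small pass-through episode file (one hospitalization per fifth patient)."""
    rng = random.Random(f"{spec.seed}-episodes")
    institutions = sorted(INSTITUTIONS)
    episodes = []
    for i in range(0, spec.n_patients, 5):
        year = rng.choice(spec.year_list)
        admit = _rand_date(rng, year)
        episodes.append(
            EpisodeRecord(
                patient_id=f"PT{i:05d}",
                episode_id=f"EP{i:05d}",
                admission_date=admit,
                discharge_date=admit + dt.timedelta(days=rng.randint(0, 14)),
                admission_source=rng.choice(("emergency", "elective", "transfer")),
                discharge_disposition=rng.choice(("home", "snf", "transfer")),
                demographics=f"age_band={rng.choice(('0-17', '18-44', '45-64', '65+'))}",
            )
        )
    return episodes


LEDGER_COLUMNS = ("line_id", "stratum", "expected_method", "expected_cost_nominal", "final_billed")


def write_ledger(ledger: Sequence[LedgerEntry], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(LEDGER_COLUMNS)
        for entry in ledger:
            writer.writerow(
                [
                    entry.line_id,
                    entry.stratum,
                    entry.expected_method.value,
                    str(entry.expected_cost_nominal),
                    "1" if entry.final_billed else "0",
                ]
            )


def read_ledger(path: str | Path) -> list[LedgerEntry]:
    out = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(
                LedgerEntry(
                    line_id=row["line_id"],
                    stratum=row["stratum"],
                    expected_method=CostMethod(row["expected_method"]),
                    expected_cost_nominal=Decimal(row["expected_cost_nominal"]),
                    final_billed=row["final_billed"] == "1",
                )
            )
    return out


def write_fixture_set(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write a complete fixture set: reference bundle, extract, ledger, episodes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    refs = generate_reference_bundle(spec)
    lines, ledger = generate_billing_extract(spec, refs)
    episodes = generate_episodes(spec)
    paths = {
        "refs": out_dir / "refs",
        "extract": out_dir / "extract.csv",
        "ledger": out_dir / "ledger.csv",
        "episodes": out_dir / "episodes.csv",
    }
    refs.save(paths["refs"])
    write_billing_extract(lines, paths["extract"])
    write_ledger(ledger, paths["ledger"])
    write_episodes(episodes, paths["episodes"])
    return paths
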