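"""Billing domain types and the delimited interchange formats.

Service lines come out of institutional decision-support-system (DSS) extracts:
one row per billed service with a procedure code (HCPCS/CPT-4), up to four
modifiers, a UB revenue code for facility lines, place of service, quantity,
charge, and a final-billed indicator.  Institutions differ in column naming and
encodings, so reading goes through a :class:`DialectConfig` that maps the
source's columns and value encodings onto the canonical layout.

All files are delimited UTF-8 text with a header row.  Dates are ISO-8601 and
currency is decimal text with two fractional digits.
"""

from __future__ import annotations

import csv
import datetime as dt
import logging
from dataclasses import dataclass, field
from decimal import Decimal, InvalidOperation
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from ._money import D, fmt_money, sign
from .errors import ContractError, FormatError

log = logging.getLogger(__name__)


class PlaceOfService(str, Enum):
    FACILITY = "facility"
    NONFACILITY = "nonfacility"


class ClaimForm(str, Enum):
    """Billing form that routes a line to the professional or hospital algorithm."""

    PROFESSIONAL = "CMS1500"
    HOSPITAL = "UB04"


class CostMethod(str, Enum):
    """Costing methodology assigned to every line, exactly one per line."""

    PFS = "PFS"
    LABORATORY = "laboratory"
    DME = "DME"
    DRUG = "drug"
    GAP = "gap"
    ANESTHESIA = "anesthesia"
    CCR = "CCR"
    ZERO_CHARGE = "zero_charge"
    IMPUTE = "impute"
    HEADER = "header"


#: methods produced by the professional decision tree
PROFESSIONAL_METHODS = frozenset(
    {
        CostMethod.PFS,
        CostMethod.LABORATORY,
        CostMethod.DME,
        CostMethod.DRUG,
        CostMethod.GAP,
        CostMethod.ANESTHESIA,
        CostMethod.IMPUTE,
        CostMethod.HEADER,
    }
)

#: fee-schedule-derived methods that feed the imputation-rate numerator
FEE_BASED_METHODS = frozenset(
    {
        CostMethod.PFS,
        CostMethod.LABORATORY,
        CostMethod.DME,
        CostMethod.DRUG,
        CostMethod.GAP,
        CostMethod.ANESTHESIA,
    }
)


@dataclass(frozen=True)
class ServiceLine:
    """One billed service line from a DSS extract.

    ``line_id`` is plumbing: an opaque row identifier used to tie costed output
    and QC findings back to the extract (and, for synthetic extracts, to the
    expected-cost ledger).
    """

    patient_id: str
    institution_id: str
    service_date: dt.date
    charge_master_code: str | None
    procedure_code: str | None
    modifiers: tuple[str, ...]
    place_of_service: PlaceOfService
    quantity: int
    charge: Decimal
    ub_revenue_code: str | None = None
    final_billed: bool = True
    claim_form: ClaimForm | None = None
    anesthesia_minutes: Decimal | None = None
    service_description: str | None = None
    line_diagnoses: tuple[str, ...] = ()
    header: bool = False
    line_id: str | None = None

    def validate(self) -> None:
        if not (self.procedure_code or self.ub_revenue_code or self.charge_master_code):
            raise ValueError(
                "line carries none of procedure_code / ub_revenue_code / charge_master_code"
            )
        if len(self.modifiers) > 4:
            raise ValueError(f"{len(self.modifiers)} modifiers present; at most 4 allowed")
        if sign(self.charge) * sign(self.quantity) < 0:
            raise ValueError(
                f"charge {self.charge} and quantity {self.quantity} disagree in sign"
            )
        if self.anesthesia_minutes is not None and self.anesthesia_minutes < 0:
            raise ValueError("anesthesia_minutes must be non-negative")

    @property
    def service_year(self) -> int:
        return self.service_date.year

    def is_hospital(self) -> bool:
        """Route by billing form; absent a form, a UB revenue code marks a facility line."""
        if self.claim_form is not None:
            return self.claim_form is ClaimForm.HOSPITAL
        return self.ub_revenue_code is not None


@dataclass(frozen=True)
class CostedServiceLine:
    """A service line plus its standardized cost and costing-method label.

    ``cost_inflated`` / ``inflation_target_year`` are filled by the inflation
    step; ``ccr_provenance`` records how a hospital line's ratio was resolved
    (``mapped`` / ``hospital_average`` / ``prior_year``).
    """

    line: ServiceLine
    cost_nominal: Decimal
    cost_method: CostMethod
    cost_inflated: Decimal | None = None
    inflation_target_year: int | None = None
    ccr_provenance: str | None = None

    def __post_init__(self) -> None:
        if self.line.charge == 0 and self.cost_method is CostMethod.ZERO_CHARGE:
            if self.cost_nominal != 0:
                raise ValueError("zero-charge line must carry zero cost")
        if self.cost_nominal != 0 and sign(self.cost_nominal) != sign(self.line.charge):
            # billing corrections carry negative charge and negative cost
            raise ValueError(
                f"cost {self.cost_nominal} and charge {self.line.charge} disagree in sign"
            )


@dataclass(frozen=True)
class EpisodeRecord:
    """One hospitalization / billing episode, passed through from the source."""

    patient_id: str
    episode_id: str
    admission_date: dt.date
    discharge_date: dt.date
    admission_source: str = ""
    discharge_disposition: str = ""
    demographics: str = ""

    def __post_init__(self) -> None:
        if self.admission_date > self.discharge_date:
            raise ValueError("admission_date must not exceed discharge_date")


@dataclass(frozen=True)
class CohortRequest:
    """Investigator request: patients, service-date window(s), inflation target year.

    ``date_ranges`` may be a single global ``(start, end)`` interval or a
    per-patient mapping of intervals.
    """

    patient_ids: frozenset[str]
    date_ranges: tuple[dt.date, dt.date] | Mapping[str, tuple[dt.date, dt.date]]
    target_year: int

    def __post_init__(self) -> None:
        ranges = (
            [self.date_ranges]
            if isinstance(self.date_ranges, tuple)
            else list(self.date_ranges.values())
        )
        for start, end in ranges:
            if start > end:
                raise ValueError(f"date range start {start} after end {end}")

    def covers(self, patient_id: str, date: dt.date) -> bool:
        if patient_id not in self.patient_ids:
            return False
        if isinstance(self.date_ranges, tuple):
            start, end = self.date_ranges
        else:
            if patient_id not in self.date_ranges:
                return False
            start, end = self.date_ranges[patient_id]
        return start <= date <= end


# ---------------------------------------------------------------------------
# dialect configuration


CANONICAL_COLUMNS = (
    "line_id",
    "patient_id",
    "institution_id",
    "service_date",
    "charge_master_code",
    "procedure_code",
    "modifiers",
    "place_of_service",
    "quantity",
    "charge",
    "ub_revenue_code",
    "final_billed",
    "claim_form",
    "anesthesia_minutes",
    "service_description",
    "line_diagnoses",
)

MANDATORY_COLUMNS = (
    "patient_id",
    "service_date",
    "charge_master_code",
    "procedure_code",
    "modifiers",
    "place_of_service",
    "quantity",
    "charge",
    "ub_revenue_code",
    "final_billed",
)


@dataclass(frozen=True)
class DialectConfig:
    """Maps one institution's extract onto the canonical layout.

    ``column_map`` maps canonical names to the source file's column names;
    unmapped canonical names are assumed to use the canonical name itself.
    ``place_map`` translates the source's place-of-service encoding (the usual
    source encoding is "hospital" vs "clinic") and ``claim_form_map`` its
    billing-form encoding.  Lines whose charge-master code starts with
    ``header_charge_master_prefix`` are flagged as header lines and costed at
    zero with the ``header`` method.
    """

    name: str = "canonical"
    delimiter: str = ","
    column_map: Mapping[str, str] = field(default_factory=dict)
    place_map: Mapping[str, PlaceOfService] = field(
        default_factory=lambda: {
            "facility": PlaceOfService.FACILITY,
            "nonfacility": PlaceOfService.NONFACILITY,
            "hospital": PlaceOfService.FACILITY,
            "clinic": PlaceOfService.NONFACILITY,
        }
    )
    claim_form_map: Mapping[str, ClaimForm] = field(
        default_factory=lambda: {
            "CMS1500": ClaimForm.PROFESSIONAL,
            "UB04": ClaimForm.HOSPITAL,
            "CMS1450": ClaimForm.HOSPITAL,
        }
    )
    true_values: frozenset[str] = frozenset({"1", "true", "True", "Y", "y", "yes"})
    false_values: frozenset[str] = frozenset({"0", "false", "False", "N", "n", "no", ""})
    header_charge_master_prefix: str | None = None
    default_institution_id: str = "UNKNOWN"

    def source_column(self, canonical: str) -> str:
        return self.column_map.get(canonical, canonical)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DialectConfig":
        raw = yaml.safe_load(Path(path).read_text())
        kwargs: dict = {}
        for key in ("name", "delimiter", "column_map", "header_charge_master_prefix",
                    "default_institution_id"):
            if key in raw:
                kwargs[key] = raw[key]
        if "place_map" in raw:
            kwargs["place_map"] = {k: PlaceOfService(v) for k, v in raw["place_map"].items()}
        if "claim_form_map" in raw:
            kwargs["claim_form_map"] = {k: ClaimForm(v) for k, v in raw["claim_form_map"].items()}
        if "true_values" in raw:
            kwargs["true_values"] = frozenset(raw["true_values"])
        if "false_values" in raw:
            kwargs["false_values"] = frozenset(raw["false_values"])
        return cls(**kwargs)


DEFAULT_DIALECT = DialectConfig()


# ---------------------------------------------------------------------------
# readers / writers


@dataclass
class BillingReadResult:
    """Accepted lines plus per-row rejections; no row is silently dropped."""

    lines: list[ServiceLine]
    rejected: list[tuple[int, str]]  # (1-based file line number, message)


def _parse_date(text: str) -> dt.date:
    return dt.date.fromisoformat(text.strip())


def _parse_bool(text: str, dialect: DialectConfig) -> bool:
    text = text.strip()
    if text in dialect.true_values:
        return True
    if text in dialect.false_values:
        return False
    raise ValueError(f"unrecognized boolean value {text!r}")


def read_billing_extract(
    path: str | Path, dialect: DialectConfig = DEFAULT_DIALECT
) -> BillingReadResult:
    """Read a DSS billing extract into validated :class:`ServiceLine` objects.

    Raises :class:`FormatError` if a mandatory column is missing.  Rows that
    fail parsing or a billing invariant are collected in ``rejected`` with
    their file line number; valid rows are never lost.
    """
    path = Path(path)
    lines: list[ServiceLine] = []
    rejected: list[tuple[int, str]] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=dialect.delimiter)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, no header row")
        header = set(reader.fieldnames)
        for canonical in MANDATORY_COLUMNS:
            if dialect.source_column(canonical) not in header:
                raise FormatError(
                    f"{path}: missing mandatory column "
                    f"{dialect.source_column(canonical)!r} (canonical {canonical!r})"
                )
        for row in reader:
            line_no = reader.line_num
            try:
                lines.append(_row_to_line(row, dialect))
            except (ValueError, InvalidOperation, KeyError) as exc:
                rejected.append((line_no, str(exc)))
    if rejected:
        log.warning("%s: rejected %d row(s)", path, len(rejected))
    return BillingReadResult(lines=lines, rejected=rejected)


def _get(row: Mapping[str, str], dialect: DialectConfig, canonical: str) -> str:
    return (row.get(dialect.source_column(canonical)) or "").strip()


def _row_to_line(row: Mapping[str, str], dialect: DialectConfig) -> ServiceLine:
    modifiers_raw = _get(row, dialect, "modifiers")
    modifiers = tuple(m.strip() for m in modifiers_raw.split(";") if m.strip())
    place_raw = _get(row, dialect, "place_of_service")
    if place_raw not in dialect.place_map:
        raise ValueError(f"unrecognized place of service {place_raw!r}")
    claim_raw = _get(row, dialect, "claim_form")
    claim_form = dialect.claim_form_map.get(claim_raw) if claim_raw else None
    minutes_raw = _get(row, dialect, "anesthesia_minutes")
    diagnoses_raw = _get(row, dialect, "line_diagnoses")
    charge_master = _get(row, dialect, "charge_master_code") or None
    prefix = dialect.header_charge_master_prefix
    line = ServiceLine(
        line_id=_get(row, dialect, "line_id") or None,
        patient_id=_get(row, dialect, "patient_id"),
        institution_id=_get(row, dialect, "institution_id") or dialect.default_institution_id,
        service_date=_parse_date(_get(row, dialect, "service_date")),
        charge_master_code=charge_master,
        procedure_code=_get(row, dialect, "procedure_code") or None,
        modifiers=modifiers,
        place_of_service=dialect.place_map[place_raw],
        quantity=int(_get(row, dialect, "quantity")),
        charge=Decimal(_get(row, dialect, "charge")),
        ub_revenue_code=_get(row, dialect, "ub_revenue_code") or None,
        final_billed=_parse_bool(_get(row, dialect, "final_billed"), dialect),
        claim_form=claim_form,
        anesthesia_minutes=Decimal(minutes_raw) if minutes_raw else None,
        service_description=_get(row, dialect, "service_description") or None,
        line_diagnoses=tuple(d.strip() for d in diagnoses_raw.split(";") if d.strip()),
        header=bool(prefix and charge_master and charge_master.startswith(prefix)),
    )
    line.validate()
    return line


def _line_to_row(line: ServiceLine) -> dict[str, str]:
    return {
        "line_id": line.line_id or "",
        "patient_id": line.patient_id,
        "institution_id": line.institution_id,
        "service_date": line.service_date.isoformat(),
        "charge_master_code": line.charge_master_code or "",
        "procedure_code": line.procedure_code or "",
        "modifiers": ";".join(line.modifiers),
        "place_of_service": line.place_of_service.value,
        "quantity": str(line.quantity),
        "charge": fmt_money(line.charge),
        "ub_revenue_code": line.ub_revenue_code or "",
        "final_billed": "1" if line.final_billed else "0",
        "claim_form": line.claim_form.value if line.claim_form else "",
        "anesthesia_minutes": str(line.anesthesia_minutes) if line.anesthesia_minutes is not None else "",
        "service_description": line.service_description or "",
        "line_diagnoses": ";".join(line.line_diagnoses),
    }


def write_billing_extract(lines: Iterable[ServiceLine], path: str | Path) -> None:
    """Write service lines in the canonical extract layout."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(CANONICAL_COLUMNS))
        writer.writeheader()
        for line in lines:
            writer.writerow(_line_to_row(line))


COSTED_COLUMNS = CANONICAL_COLUMNS + (
    "cost_nominal",
    "cost_inflated",
    "cost_method",
    "inflation_target_year",
    "ccr_provenance",
)


def write_costed_lines(lines: Sequence[CostedServiceLine], path: str | Path) -> None:
    """Write the costed service-line ledger (the dataset handed to investigators).

    All lines must share one inflation target year.  The schema carries
    standardized costs only — never payer, reimbursement, or internal-cost
    columns.
    """
    years = {c.inflation_target_year for c in lines}
    if len(years) > 1:
        raise ContractError(f"mixed inflation target years in one output: {sorted(years)}")
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(COSTED_COLUMNS))
        writer.writeheader()
        for costed in lines:
            row = _line_to_row(costed.line)
            row["cost_nominal"] = fmt_money(costed.cost_nominal)
            row["cost_inflated"] = (
                fmt_money(costed.cost_inflated) if costed.cost_inflated is not None else ""
            )
            row["cost_method"] = costed.cost_method.value
            row["inflation_target_year"] = (
                str(costed.inflation_target_year) if costed.inflation_target_year else ""
            )
            row["ccr_provenance"] = costed.ccr_provenance or ""
            writer.writerow(row)


def read_costed_lines(
    path: str | Path, dialect: DialectConfig = DEFAULT_DIALECT
) -> list[CostedServiceLine]:
    """Read back a costed ledger written by :func:`write_costed_lines`."""
    out: list[CostedServiceLine] = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, no header row")
        for row in reader:
            line = _row_to_line(row, dialect)
            out.append(
                CostedServiceLine(
                    line=line,
                    cost_nominal=Decimal(row["cost_nominal"]),
                    cost_inflated=Decimal(row["cost_inflated"]) if row["cost_inflated"] else None,
                    cost_method=CostMethod(row["cost_method"]),
                    inflation_target_year=(
                        int(row["inflation_target_year"]) if row["inflation_target_year"] else None
                    ),
                    ccr_provenance=row.get("ccr_provenance") or None,
                )
            )
    return out


def filter_final_billed(lines: Sequence[ServiceLine]) -> list[ServiceLine]:
    """Keep only final-billed lines (the definitive claim submissions)."""
    kept = [line for line in lines if line.final_billed]
    removed = len(lines) - len(kept)
    if removed:
        log.info("dropped %d non-final-billed line(s) of %d", removed, len(lines))
    return kept


EPISODE_COLUMNS = (
    "episode_id",
    "patient_id",
    "admission_date",
    "discharge_date",
    "admission_source",
    "discharge_disposition",
    "demographics",
)


def write_episodes(episodes: Iterable[EpisodeRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(EPISODE_COLUMNS))
        writer.writeheader()
        for ep in episodes:
            writer.writerow(
                {
                    "episode_id": ep.episode_id,
                    "patient_id": ep.patient_id,
                    "admission_date": ep.admission_date.isoformat(),
                    "discharge_date": ep.discharge_date.isoformat(),
                    "admission_source": ep.admission_source,
                    "discharge_disposition": ep.discharge_disposition,
                    "demographics": ep.demographics,
                }
            )


def read_episodes(path: str | Path) -> list[EpisodeRecord]:
    out = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(
                EpisodeRecord(
                    episode_id=row["episode_id"],
                    patient_id=row["patient_id"],
                    admission_date=_parse_date(row["admission_date"]),
                    discharge_date=_parse_date(row["discharge_date"]),
                    admission_source=row.get("admission_source", ""),
                    discharge_disposition=row.get("discharge_disposition", ""),
                    demographics=row.get("demographics", ""),
                )
            )
    return out
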