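"""Cohort costing pipeline and quality control.

The pipeline mirrors the warehouse's request flow: authorize the requested
patients, extract their final-billed service lines for the requested date
ranges, route each line to the professional or hospital algorithm, inflate
every cost to the request's target year as the last step, and emit the costed
ledger, the episode file, and a QC report.  Standardized costs are never
stored: each request recomputes them from source extracts and the versioned
reference bundle, so identical inputs give identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from decimal import Decimal
from pathlib import Path
from typing import Callable, Sequence

import pandas as pd

from ._money import round_cents
from .billing_model import (
    CohortRequest,
    CostedServiceLine,
    CostMethod,
    DialectConfig,
    DEFAULT_DIALECT,
    EpisodeRecord,
    ServiceLine,
    filter_final_billed,
    read_billing_extract,
    read_episodes,
    write_costed_lines,
    write_episodes,
)
from .errors import AuthorizationError, PipelineError
from .hospital_costing import cost_hospital_line
from .professional_costing import cost_professional_line
from .reference_data import (
    FEE_BASED_METHODS,
    ReferenceBundle,
    compute_imputation_rate,
)

log = logging.getLogger(__name__)

ALLOW_ALL: Callable[[str], bool] = lambda patient_id: True


def cost_line(line: ServiceLine, refs: ReferenceBundle) -> CostedServiceLine:
    """Route one line to the hospital or professional algorithm and cost it."""
    if line.is_hospital():
        table = refs.ccr_by_institution.get(line.institution_id)
        if table is None:
            raise PipelineError(
                f"no CCR table for institution {line.institution_id!r}"
            )
        return cost_hospital_line(line, table)
    return cost_professional_line(line, refs)


def cost_lines(lines: Sequence[ServiceLine], refs: ReferenceBundle) -> list[CostedServiceLine]:
    return [cost_line(line, refs) for line in lines]


def apply_inflation(
    lines: Sequence[CostedServiceLine], target_year: int, index_table
) -> list[CostedServiceLine]:
    """Inflate nominal costs to the target year; the last step of the algorithm.

    cost_inflated = cost_nominal × deflator(target) / deflator(service year),
    rounded to cents per line.
    """
    out = []
    for costed in lines:
        factor = index_table.index(costed.line.service_year, target_year)
        out.append(
            dataclasses.replace(
                costed,
                cost_inflated=round_cents(costed.cost_nominal * factor),
                inflation_target_year=target_year,
            )
        )
    return out


def build_imputation_rates(
    lines: Sequence[ServiceLine], refs: ReferenceBundle
) -> dict[tuple[str, int], Decimal]:
    """Derive imputation rates from a full institution-year costing pass.

    Runs the professional algorithm over all lines, keeps the fee-based
    results (fee schedules and anesthesia, excluding zero charges), and forms
    Σ assigned cost / Σ charge per (institution, year).  Rates are then frozen
    into the reference bundle; cohort runs never recompute them from a cohort
    subset.
    """
    by_key: dict[tuple[str, int], list[CostedServiceLine]] = {}
    for line in lines:
        if line.is_hospital():
            continue
        try:
            costed = cost_professional_line(line, refs)
        except PipelineError:
            continue  # would impute: not part of the rate's numerator
        if costed.cost_method in FEE_BASED_METHODS and line.charge != 0:
            by_key.setdefault((line.institution_id, line.service_year), []).append(costed)
    return {
        key: compute_imputation_rate(group, institution_id=key[0], year=key[1]).rate
        for key, group in by_key.items()
    }


# ---------------------------------------------------------------------------
# quality control


@dataclass
class QCReport:
    """Quality-control findings over one costed dataset."""

    n_lines: int
    unmapped_revenue_codes: list[tuple[str, int]]
    imputed_procedure_codes: list[tuple[str, int]]
    method_proportions: dict[str, dict[str, float]]  # stratum -> method -> % of stratum
    stratum_shares: dict[str, float]  # stratum -> % of total lines
    yearly_trends: list[tuple[int, Decimal, Decimal]]  # (year, Σcharge, Σcost_nominal)
    provenance_counts: dict[str, int]
    rejected_rows: int = 0

    def to_dict(self) -> dict:
        return {
            "n_lines": self.n_lines,
            "unmapped_revenue_codes": [list(t) for t in self.unmapped_revenue_codes],
            "imputed_procedure_codes": [list(t) for t in self.imputed_procedure_codes],
            "method_proportions": self.method_proportions,
            "stratum_shares": self.stratum_shares,
            "yearly_trends": [
                {"year": y, "total_charge": str(ch), "total_cost_nominal": str(co)}
                for y, ch, co in self.yearly_trends
            ],
            "provenance_counts": self.provenance_counts,
            "rejected_rows": self.rejected_rows,
        }

    def to_text(self) -> str:
        parts = [f"QC report over {self.n_lines} costed lines"]
        parts.append("\nStratum shares (% of total lines):")
        for stratum, share in sorted(self.stratum_shares.items()):
            parts.append(f"  {stratum:<14} {share:6.1f}")
        parts.append("\nCost-method proportions (% within stratum):")
        for stratum, methods in sorted(self.method_proportions.items()):
            parts.append(f"  {stratum}:")
            for method, pct in sorted(methods.items()):
                parts.append(f"    {method:<14} {pct:6.1f}")
        parts.append("\nCCR lookup provenance:")
        for prov, count in sorted(self.provenance_counts.items()):
            parts.append(f"  {prov:<18} {count}")
        parts.append("\nRevenue codes missing from the CCR reference file:")
        for code, count in self.unmapped_revenue_codes:
            parts.append(f"  {code}  ({count} lines)")
        if not self.unmapped_revenue_codes:
            parts.append("  (none)")
        parts.append("\nImputed procedure codes:")
        for code, count in self.imputed_procedure_codes:
            parts.append(f"  {code}  ({count} lines)")
        if not self.imputed_procedure_codes:
            parts.append("  (none)")
        parts.append("\nYearly totals (charges vs nominal costs):")
        for year, charge, cost in self.yearly_trends:
            parts.append(f"  {year}  charge {charge}  cost {cost}")
        return "\n".join(parts)


def _stratum(costed: CostedServiceLine) -> str:
    return "hospital" if costed.line.is_hospital() else "professional"


def cost_method_distribution(lines: Sequence[CostedServiceLine]) -> pd.DataFrame:
    """Two-level cost-method distribution: % of total lines per stratum, and
    % of each stratum by method (the warehouse's standard summary layout)."""
    records = [
        {"stratum": _stratum(c), "cost_method": c.cost_method.value} for c in lines
    ]
    if not records:
        return pd.DataFrame(columns=["stratum", "cost_method", "pct_of_total", "pct_of_stratum"])
    df = pd.DataFrame.from_records(records)
    n_total = len(df)
    rows = []
    for stratum, group in df.groupby("stratum"):
        n_stratum = len(group)
        rows.append(
            {
                "stratum": stratum,
                "cost_method": "(all)",
                "pct_of_total": 100.0 * n_stratum / n_total,
                "pct_of_stratum": 100.0,
            }
        )
        for method, sub in group.groupby("cost_method"):
            rows.append(
                {
                    "stratum": stratum,
                    "cost_method": method,
                    "pct_of_total": 100.0 * len(sub) / n_total,
                    "pct_of_stratum": 100.0 * len(sub) / n_stratum,
                }
            )
    return pd.DataFrame(rows).sort_values(["stratum", "cost_method"]).reset_index(drop=True)


def qc_report(
    lines: Sequence[CostedServiceLine], refs: ReferenceBundle, rejected_rows: int = 0
) -> QCReport:
    """Build the QC report: unmapped revenue codes, imputed codes, proportions,
    provenance tallies, and per-year charge/cost trends."""
    unmapped: dict[str, int] = {}
    imputed: dict[str, int] = {}
    provenance: dict[str, int] = {}
    trends: dict[int, list[Decimal]] = {}
    strata_counts: dict[str, dict[str, int]] = {}
    for costed in lines:
        line = costed.line
        stratum = _stratum(costed)
        strata_counts.setdefault(stratum, {})
        strata_counts[stratum][costed.cost_method.value] = (
            strata_counts[stratum].get(costed.cost_method.value, 0) + 1
        )
        year_totals = trends.setdefault(line.service_year, [Decimal(0), Decimal(0)])
        year_totals[0] += line.charge
        year_totals[1] += costed.cost_nominal
        if costed.cost_method is CostMethod.IMPUTE and line.procedure_code:
            imputed[line.procedure_code] = imputed.get(line.procedure_code, 0) + 1
        if costed.ccr_provenance:
            provenance[costed.ccr_provenance] = provenance.get(costed.ccr_provenance, 0) + 1
        if costed.cost_method is CostMethod.CCR:
            table = refs.ccr_by_institution.get(line.institution_id)
            code = line.ub_revenue_code
            if code is None:
                unmapped["(missing)"] = unmapped.get("(missing)", 0) + 1
            elif table is not None and not any(c == code for _, c in table.entries):
                unmapped[code] = unmapped.get(code, 0) + 1
    method_proportions = {
        stratum: {
            method: 100.0 * count / sum(counts.values()) for method, count in counts.items()
        }
        for stratum, counts in strata_counts.items()
    }
    n = len(lines)
    stratum_shares = {
        stratum: 100.0 * sum(counts.values()) / n for stratum, counts in strata_counts.items()
    } if n else {}
    return QCReport(
        n_lines=n,
        unmapped_revenue_codes=sorted(unmapped.items()),
        imputed_procedure_codes=sorted(imputed.items()),
        method_proportions=method_proportions,
        stratum_shares=stratum_shares,
        yearly_trends=[(y, t[0], t[1]) for y, t in sorted(trends.items())],
        provenance_counts=provenance,
        rejected_rows=rejected_rows,
    )


# ---------------------------------------------------------------------------
# cohort request flow


@dataclass
class CohortResult:
    costed: list[CostedServiceLine]
    episodes: list[EpisodeRecord]
    qc: QCReport
    bundle_hash: str


def run_cohort_costing(
    request: CohortRequest,
    billing_paths: Sequence[str | Path],
    refs: ReferenceBundle,
    authorize: Callable[[str], bool] = ALLOW_ALL,
    episode_path: str | Path | None = None,
    out_dir: str | Path | None = None,
    dialect: DialectConfig = DEFAULT_DIALECT,
) -> CohortResult:
    """Extract, cost, inflate, and report a cohort.

    Only final-billed lines belonging to requested patients within their
    requested date ranges are costed.  Fails before producing any output if a
    patient is unauthorized or the reference bundle does not cover every
    service year in range.
    """
    unauthorized = {p for p in request.patient_ids if not authorize(p)}
    if unauthorized:
        raise AuthorizationError(unauthorized)

    lines: list[ServiceLine] = []
    rejected = 0
    for path in billing_paths:
        result = read_billing_extract(path, dialect)
        lines.extend(result.lines)
        rejected += len(result.rejected)
    lines = filter_final_billed(lines)
    lines = [l for l in lines if request.covers(l.patient_id, l.service_date)]

    needed_years = {l.service_year for l in lines} | {request.target_year}
    missing = needed_years - refs.inflation.years
    if missing:
        raise PipelineError(f"reference bundle missing inflation years: {sorted(missing)}")

    costed = cost_lines(lines, refs)
    costed = apply_inflation(costed, request.target_year, refs.inflation)
    qc = qc_report(costed, refs, rejected_rows=rejected)
    log.info(
        "costed %d lines for %d patient(s); methods: %s",
        len(costed), len(request.patient_ids),
        {s: dict(sorted(m.items())) for s, m in qc.method_proportions.items()},
    )

    episodes: list[EpisodeRecord] = []
    if episode_path is not None:
        episodes = [
            ep for ep in read_episodes(episode_path) if ep.patient_id in request.patient_ids
        ]

    bundle_hash = refs.manifest_hash
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_costed_lines(costed, out_dir / "costed_lines.csv")
        write_episodes(episodes, out_dir / "episodes.csv")
        (out_dir / "qc_report.json").write_text(
            json.dumps(qc.to_dict(), indent=2, sort_keys=True) + "\n"
        )
        (out_dir / "run_info.json").write_text(
            json.dumps(
                {
                    "target_year": request.target_year,
                    "n_patients": len(request.patient_ids),
                    "n_costed_lines": len(costed),
                    "reference_bundle_hash": bundle_hash,
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
    return CohortResult(costed=costed, episodes=episodes, qc=qc, bundle_hash=bundle_hash)
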