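"""Exception taxonomy for the costing warehouse."""


class StdcostError(Exception):
    """Base class for all package errors."""


class FormatError(StdcostError):
    """A delimited file is structurally unusable (e.g. a mandatory column is missing)."""


class RowValidationError(StdcostError):
    """A single row violates a billing invariant; carries the 1-based line number."""

    def __init__(self, line_no: int, message: str):
        super().__init__(f"line {line_no}: {message}")
        self.line_no = line_no


class ContractError(StdcostError):
    """A caller violated an operation precondition."""


class ReferenceBuildError(StdcostError):
    """A reference table cannot be built (duplicate keys, zero charges, overlaps)."""


class ReferenceLookupError(StdcostError):
    """A reference lookup cannot be resolved (missing year, empty table)."""


class PipelineError(StdcostError):
    """Cohort costing cannot proceed (missing reference coverage, missing rates)."""


class AuthorizationError(StdcostError):
    """A cohort request names patients the authorization predicate rejects."""

    def __init__(self, patient_ids):
        ids = ", ".join(sorted(patient_ids))
        super().__init__(f"unauthorized patient(s): {ids}")
        self.patient_ids = frozenset(patient_ids)


class GenerationError(StdcostError):
    """The synthetic fixture request is infeasible."""
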