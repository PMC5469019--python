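"""Hospital (UB-04) service costing.

Medicare pays facilities prospectively, so reimbursement cannot price
individual facility services; instead each billed charge is converted to a
standardized cost by a cost-to-charge ratio (CCR) resolved at the cost-center
level through the UB-revenue-code crosswalk.  Charges on facility lines
already reflect quantity, so quantity is not multiplied in again.
"""

from __future__ import annotations

import logging
from decimal import Decimal

from ._money import round_cents
from .billing_model import CostedServiceLine, CostMethod, ServiceLine
from .reference_data import CCRTable, lookup_ccr

log = logging.getLogger(__name__)


def cost_hospital_line(line: ServiceLine, ccr: CCRTable) -> CostedServiceLine:
    """Cost one hospital line: charge × resolved CCR, cents-rounded.

    Zero charges cost zero (method ``zero_charge``); otherwise the method is
    ``CCR`` with the lookup provenance (mapped / hospital_average /
    prior_year) recorded on the line.  A non-zero-charge line with no revenue
    code is costed at the hospital average and flagged for QC via its
    ``hospital_average`` provenance plus a warning.
    """
    if line.charge == 0:
        return CostedServiceLine(
            line=line, cost_nominal=Decimal("0.00"), cost_method=CostMethod.ZERO_CHARGE
        )
    if line.ub_revenue_code is None:
        log.warning(
            "hospital line %s has no UB revenue code; costing at hospital average",
            line.line_id or line.patient_id,
        )
    ratio, provenance = lookup_ccr(ccr, line.ub_revenue_code, line.service_year)
    cost = round_cents(line.charge * ratio)
    log.debug(
        "hospital line %s: charge %s x CCR %s (%s) -> %s",
        line.line_id, line.charge, ratio, provenance.value, cost,
    )
    return CostedServiceLine(
        line=line,
        cost_nominal=cost,
        cost_method=CostMethod.CCR,
        ccr_provenance=provenance.value,
    )
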