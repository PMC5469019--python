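# Methods

## The costing model

stdcost implements service-line microcosting from an institutional
perspective: every billed service receives a *standardized* cost — a
relative dollar valuation drawn from national reimbursement schedules or
cost-report ratios — rather than an internal cost or a payment.  The model
assumes the source billing extract is a final-billed, line-level ledger in
which professional lines carry HCPCS/CPT-4 codes and up to four modifiers,
and hospital lines carry UB revenue codes whose charges already reflect
quantity.  Costs are deliberately *not* payments: prospective (DRG-style)
payment is rejected as a price source for facility services because it
cannot be attributed to individual service lines.

Routing is by billing form: CMS-1500 lines follow the professional decision
tree, UB-04 lines the CCR route.  When the extract does not record the form,
the presence of a UB revenue code marks a facility line.

### Professional services

The professional tree evaluates, in order: header flag → zero charge →
anesthesia → fee-schedule match → imputation.  The ordering embodies two
assumptions: header and zero-charge rules are bookkeeping conventions that
preempt pricing, and anesthesia codes have no meaningful schedule fee (they
are time-priced), so they never reach the fee lookup.

Fee lookup walks the stacked schedule in fixed source precedence
PFS → laboratory → DMEPOS → PEN → drug ASP → gap.  The precedence is a
design choice: Medicare-assigned fees are consulted before the commercial
gap schedule, which exists precisely for codes Medicare leaves carrier-
priced.  Within a source, a fee-selecting modifier (26 professional
component, TC technical component, 53 discontinued procedure) prefers the
modifier-specific row over the base row; 26 is tried before TC before 53 on
the rare line carrying more than one.  A matched fee of exactly zero is
treated as "not mappable to a non-zero fee" and falls through to imputation
rather than producing a zero cost, mirroring the imputation rate's own
definition.

Percentage modifiers (bilateral 150%, multiple procedure 50%, cosurgeon
62.5%, surgery assistant AS/80/81/82 16%) compound multiplicatively when
several appear.  Multiplication commutes, so the result is order-free;
whether percentages apply before or after quantity multiplication is equally
immaterial and the implementation applies them after.  Quantity enters as
fee × |quantity| with the quantity's sign re-applied, so billing corrections
(negative charge and quantity) yield negative costs.

Anesthesia: cost = (base units by CPT-4 code + minutes/15 rounded to 0.1 +
ASA physical-status units) × the year's national-average conversion factor.
The medical-direction modifiers QK, QX, QY halve the cost at most once per
line — the reduction models a single "more than one clinician" event, not a
stackable discount.  When minutes are missing but the institution's billing
conversion factor is known, the equivalent charge-conversion route is used:
charge ÷ billing factor × Medicare factor.  No direction reduction is
re-applied on that route, because the billed charge already reflects the
billed (possibly reduced) units.

Imputation rates are computed in a prior pass over a full institution-year
(`build_imputation_rates`), frozen into the reference bundle, and never
recomputed from a cohort subset — otherwise two cohorts from the same year
would price the same line differently.  Already-imputed lines qualify for
the ratio alongside fee-costed lines, which makes the construction a
fixpoint: recomputing the rate from lines imputed at rate r returns r.

### Hospital services

cost = charge × CCR, where the CCR is a pooled moving average: Σ costs /
Σ charges of the revenue code's cost center over the report-year window
(default 3 years), hospitals of one institution combined before pooling.
Pooling costs and charges first — rather than averaging yearly ratios —
weights years by volume and is robust to a small-charge year producing an
extreme ratio.  The window truncates at the start of the series so early
years remain costable.  Fallbacks: an unmapped revenue code takes the
hospital-average ratio; a service year past the last report carries the most
recent report year forward (cost reports lag about a year).  Every fallback
is recorded as per-line provenance (`mapped` / `hospital_average` /
`prior_year`) and tallied by QC.  A service year *before* the first report
raises instead of extrapolating backwards.

### Inflation

index(service_year, target_year) = GDP deflator(target) / deflator(service),
applied to nominal costs as the last step.  The identity index(y,y)=1 and
multiplicative transitivity hold exactly up to decimal precision (tested to
1e-12).

## Numerical choices

All money is `decimal.Decimal`; files carry 2-decimal strings, never binary
floats.  Rounding is half-away-from-zero, applied once per line at the end
of its computation (and to 0.1 for anesthesia time units: 40 min → 2.666… →
2.7).  Because rounding is symmetric, negating a charge exactly negates the
cost, which keeps billing corrections consistent.  Per-line cent rounding
means aggregate identities (Σcost = ratio × Σcharge; inflate-then-sum =
sum-then-inflate) hold within half a cent per line, and fee-scale
homogeneity holds within one cent — the tests assert those tolerances, not
exact equality.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| CCR window | 3 | report years | smooths cost-report preparation changes between years |
| combine_hospitals | true | — | one institution's co-located hospitals share one ratio set |
| anesthesia code range | 00100–01999 | CPT-4 | the anesthesia section of CPT-4; configurable, not hard-coded |
| fee-selecting modifiers | 26, TC, 53 | — | the modifiers with dedicated fee rows |
| monetary rounding | cents, half away from zero | USD | ledger convention |

## The synthetic generator

`stdcost.fixtures` generates the whole warehouse: a stacked fee schedule
with every source represented (PFS rows with genuine facility/nonfacility
splits and 26/TC rows), the 16-modifier cost-adjustment table, anesthesia
base units and yearly conversion factors, cost reports for two institutions
(one with two combined hospitals), a revenue-code crosswalk over the
standard cost-report centers, GDP deflators, and imputation rates.  Billing
lines are constructed backwards from a chosen cost method, so the expected
method and cost of every line are known to the cent and engine checks are
exact rather than statistical.

Defaults are chosen once to resemble a large mixed billing population:
professional lines ≈ 48.6% of the total, with within-stratum method shares
dominated by PFS and laboratory lines and roughly 28% zero-charge lines in
both strata; charges on fee-matched lines are fee × Uniform(1.2, 3.0)
markup, so derived cost-to-charge ratios fall below 1; 2% of lines are
negative billing corrections; 5% are non-final claim versions; 5% of
hospital CCR lines carry deliberately unmapped revenue codes.  Test and
acceptance runs use 1,000- and 10,000-line extracts, a size at which the
method mix is well resolved while the full suite stays fast.

What the generator does **not** emulate: real CMS file dialects, charge
distribution shapes, coding error and upcoding, claim resubmission
histories, per-patient utilization correlation, or episode grouping logic.
Passing the known-answer suite therefore demonstrates that the engine
implements the costing rules exactly, not that it is robust to the full
messiness of production DSS data — that is what the QC report (unmapped
codes, imputed-code lists, trend tables) is for on real extracts.

## Other design decisions

- The "header" cost method exists in some institutions' data as a
  charge-master convention; its detection is a dialect-config rule (a
  charge-master prefix), and header lines cost zero.
- PEN (parenteral/enteral nutrition) schedule rows are labelled with the
  `DME` cost method; the method taxonomy folds PEN into the DMEPOS family.
- Authorization is a pluggable predicate on patient ids (default allow-all);
  institutional review and consent checks are site-specific.
- Costs are never persisted: each cohort request recomputes them, and the
  output carries the reference-bundle content hash for provenance.  The
  output schema contains standardized costs only — no payer, reimbursement,
  or internal-cost columns.
- Episode records pass through from the source; no admission-matching logic.

## Limitations

- Only the normalized reference-file layouts are parsed; native CMS
  distribution formats must be converted upstream.
- Constant-year repricing (valuing all services at one year's fees to remove
  fee-schedule drift from trends) is not implemented; inflation adjustment
  rescales price levels but cannot remove RVU or cost-report structure
  changes over time.
- The method is specific to US billing conventions (HCPCS/CPT-4, UB revenue
  codes, Medicare cost reports).
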