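# stdcost

**stdcost** is a standardized healthcare cost engine for health-economics and
health-services research.  It assigns an inflation-adjusted *standardized
cost* and a cost-method label to every billed service line in an
institutional billing extract — professional services billed on the CMS-1500
form and hospital services billed on the UB-04 form — so that investigators
can run bottom-up (microcosting) analyses of procedures, conditions, and care
cycles without exposing business-sensitive internal costs or payer terms.

## The costing algorithm

Professional services (HCPCS / CPT-4 coded) are priced from a stacked table
of national fee schedules — Medicare Physician Fee Schedule (PFS), clinical
laboratory, DMEPOS/PEN, Part B drug average sales price, and a commercial
"gap" schedule for carrier-priced codes.  The decision tree per line:

1. header lines → cost 0, method `header`;
2. zero charge → cost 0, method `zero_charge`;
3. anesthesia codes → cost = (base + time + physical-status units) ×
   conversion factor, where time units = minutes / 15 rounded to 0.1, ASA
   status P3/P4/P5 add 1/2/3 units, and a medical-direction modifier
   (QK/QX/QY) halves the cost once; when minutes are unrecorded the charge is
   divided by the institution's billing conversion factor and multiplied by
   the Medicare factor instead;
4. fee-schedule match with a non-zero fee → cost = fee × |quantity| ×
   modifier percentages (bilateral 150%, multiple procedure 50%, cosurgeon
   62.5%, surgery assistant 16%), signed like the quantity; place of service
   selects the facility vs nonfacility fee, and modifiers 26/TC/53 select
   modifier-specific fee rows;
5. anything left → `impute`: charge × the institution-year's average
   professional cost-to-charge rate (Σ assigned fees / Σ charges over all
   fee-costed, non-zero-charge services of that year).

Hospital services are priced as charge × a cost-center-level cost-to-charge
ratio (CCR).  CCRs are built from annual cost reports as pooled 3-year moving
averages (Σ costs / Σ charges over the window, hospitals combined), resolved
through a UB-revenue-code → cost-center crosswalk, with the hospital-average
ratio as fallback for unmapped codes and the most recent report year carried
forward while new cost reports are unavailable.

As the final step, every cost is restated in target-year dollars with the GDP
implicit price deflator: index(s, t) = deflator(t) / deflator(s).

All currency arithmetic uses exact decimals; money is rounded to cents
(half away from zero) once per line.

## Worked example

The package ships a synthetic-fixture generator that emulates a two-provider
warehouse (stacked fee schedules, cost reports, crosswalk, deflators) and
builds billing extracts *backwards* from known expected costs:

```python
from stdcost import (
    FixtureSpec, generate_reference_bundle, generate_billing_extract,
    cost_lines, apply_inflation, cost_method_distribution,
)

spec = FixtureSpec(seed=1, n_lines=2000)
refs = generate_reference_bundle(spec)
lines, ledger = generate_billing_extract(spec, refs)

costed = apply_inflation(cost_lines(lines, refs), target_year=2015,
                         index_table=refs.inflation)
for c in costed[:5]:
    l = c.line
    print(f"{l.line_id}  {l.service_date}  code={l.procedure_code or l.ub_revenue_code:<6}"
          f" charge={l.charge:>9}  cost={c.cost_nominal:>9}"
          f"  cost2015={c.cost_inflated:>9}  method={c.cost_method.value}")
```

```
L000000  2012-09-27  code=0296   charge=     0.00  cost=     0.00  cost2015=     0.00  method=zero_charge
L000001  2013-09-15  code=0314   charge=  1832.85  cost=   934.75  cost2015=   974.43  method=CCR
L000002  2013-08-22  code=0305   charge=  3809.28  cost=  1942.72  cost2015=  2025.18  method=CCR
L000003  2011-05-12  code=20105  charge=     0.00  cost=     0.00  cost2015=     0.00  method=zero_charge
L000004  2013-02-16  code=20028  charge=     0.00  cost=     0.00  cost2015=     0.00  method=zero_charge
```

Line `L000001` is a hospital laboratory charge (revenue code 0314) converted
by its cost-center CCR (934.75 / 1832.85 ≈ 0.51) and then inflated to 2015
dollars; the zero-charge lines (e.g. pharmacy-labor-style entries and bundled
visits) cost zero by rule.  The two-level cost-method distribution mirrors
the warehouse's standard QC summary:

```python
print(cost_method_distribution(costed).to_string(index=False))
```

```
     stratum cost_method  pct_of_total  pct_of_stratum
    hospital       (all)         51.15      100.000000
    hospital         CCR         36.85       72.043011
    hospital zero_charge         14.30       27.956989
professional       (all)         48.85      100.000000
professional         PFS         16.45       33.674514
professional  anesthesia          0.45        0.921187
professional        drug          0.45        0.921187
professional         gap          2.60        5.322416
professional      header          1.65        3.377687
professional      impute          0.25        0.511771
professional  laboratory         13.60       27.840328
professional zero_charge         13.40       27.430911
```

Costing the full extract against the generated bundle reproduces the
generator's expected-cost ledger exactly — method and cents — for 100% of
lines (`tests/test_acceptance.py`).

## Command line

```bash
stdcost make-fixtures --seed 9 --out fx                 # synthetic warehouse
stdcost build-refs --config refs/config.yaml --out dir  # reference bundle
stdcost cost-cohort --patients ids.txt --from 2010-01-01 --to 2014-12-31 \
    --target-year 2015 --refs fx/refs --billing fx/extract.csv --out run
stdcost qc --costed run/costed_lines.csv --refs fx/refs
```

Exit codes: 0 ok, 1 validation/authorization error, 2 pipeline error.

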