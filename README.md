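# cmpa-cea

Decision-tree cost-effectiveness model comparing two diagnostic-and-treatment
strategies for suspected cow's-milk-protein allergy (CMPA) in infants:

* **eHF-first** (standard of care): a 4-week elimination diet on extensively
  hydrolyzed formula (eHF) before the oral challenge test; children who stay
  symptomatic on eHF (≈10% of true-CMPA cases) are rescued with an extra
  4-week course of amino-acid-based formula (AAF) before their challenge.
* **AAF-first**: the elimination diet uses AAF from the start, which controls
  symptoms in essentially all true-CMPA infants; confirmed children step down
  to eHF for maintenance.

The model follows an annual national cohort of infants under 6 months
(Argentina-type demographics: 312,721 infants, 42% exclusively breastfed and
therefore excluded, 6.8% with CMPA-like symptoms, 2% with true CMPA) from
model entry to 24 months of age. Costs are monthly formula prices in USD,
band-switched at 9 months of age; effectiveness is measured in symptom-free
months. Confirmed children face cow's-milk challenge tests every 6 months,
with cumulative oral-tolerance probabilities of 56% at 12 months and 77% at
24 months; tolerant children leave the model. The package is aimed at
health-economics and pediatric-nutrition analysts who want a fully auditable,
scriptable re-implementation of this class of budget-impact/CEA analysis.

For strategies `A` (reference) and `B`, the incremental cost-effectiveness
ratio is

    ICER = (C_B − C_A) / (E_B − E_A)

with costs `C` in USD and effects `E` in symptom-free months; when `B` is
both costlier and less effective it is *dominated* and no ratio is reported.

## Worked example

```sh
$ cmpa-cea run --out out --no-timestamp
Suspected cohort: 12,334
AAF_first: cost 55,721,629 USD, symptom-free months 51,803
eHF_first: cost 59,102,149 USD, symptom-free months 51,469
AAF-first saves 3,380,520 USD and gains 334 symptom-free months (eHF-first: dominated)
```

Reading: of 312,721 infants, 131,342 exclusively breastfed children are
excluded and 12,334 of the rest enter the diagnostic pathway. Starting with
AAF instead of eHF spares the 363 expected eHF non-responders one symptomatic
4-week diagnostic window each (≈334 symptom-free months across the cohort)
and avoids ≈3.4 million USD, so the eHF-first strategy is dominated — more
expensive *and* less effective. `out/table2.csv` holds the incremental
table, `out/table3.csv` the one-way sensitivity (tornado-ordered) table;
`cmpa-cea run --trace` adds per-branch audit rows (children, duration, cost,
effect per path) to `report.json`.

One-way sensitivity: each of seven parameter ranges (formula costs ±20%,
tolerance probabilities ±25%, cohort size 11,000–14,000) is swung with the
rest at base; at every endpoint — and at the joint corner with all AAF prices
+20% and all eHF prices −20% — the AAF-first strategy remains cheaper and
more effective:

```sh
$ cmpa-cea dsa --out out     # writes out/table3.csv
```

Other subcommands: `cmpa-cea cohort` (cohort arithmetic), `cmpa-cea
consumption --weight 8 --kcal-per-kg 78` (formula-can audit: 18,720 kcal → 10
cans/month), `cmpa-cea scenarios` (seeded synthetic parameter draws).

See `docs/methods.md` for the model's accounting conventions and their
rationale.

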