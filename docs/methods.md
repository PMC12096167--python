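# Methods

## Model structure

A deterministic decision tree follows one annual cohort of suspected-CMPA
infants from model entry to 24 months of age. Both arms share a skeleton:

1. **Diagnostic window.** Every suspected child receives the arm's
   elimination formula for `diagnostic_duration_weeks` (default 4), then
   takes an oral challenge test. A negative challenge (probability
   1 − confirmed/suspected ≈ 0.706) rules CMPA out and the child exits,
   having accrued one window of formula cost and no effect (symptom-free
   months are counted for true-CMPA children only — the quantity of interest
   is symptomatic time attributable to CMPA management).
2. **Rescue (eHF-first arm only).** True-CMPA children who stay symptomatic
   on eHF (probability 1 − `ehf_effectiveness` = 0.10) receive one further
   diagnostic window on AAF before the challenge confirms them. The window
   accrues AAF cost and zero effect: symptom resolution after the formula
   switch is taken to occupy the window, so these children lose exactly one
   window of symptom-free time relative to the AAF-first arm.
3. **Maintenance.** Confirmed children are maintained to the 24-month
   horizon — a fraction `ehf_effectiveness` on eHF (step-down in the
   AAF-first arm; continued treatment in the eHF-first arm) and the rest on
   AAF. The step-down failure in the AAF-first arm is recognized at zero
   symptomatic time, so maintenance composition is identical across arms at
   base case. Challenge tests recur every `challenge_interval_months` from
   age 12; a challenge age exits children with the conditional probability
   implied by the cumulative tolerance map (56% at 12 months; (77−56)/(100−56)
   at 24; ages without a map entry, such as 18 months, carry zero incremental
   tolerance). A tolerant child stops accruing cost and, under the default
   `exit_model` convention, effect as well; `keep_effect` instead credits the
   remaining horizon as symptom-free.

Payoffs (cost USD, effect months) attach to branches and accumulate along
root-to-leaf paths; expected values come from standard rollback, with
exhaustive path enumeration kept as an independent engine oracle. Child
counts flow as continuous expectations and are rounded only for display.

## Closed-form effect delta

Maintenance is identical across arms, so the only clinical difference is who
spends the diagnostic window symptom-free. The effect delta therefore has the
closed form

    months gained = confirmed × (aaf_eff − ehf_eff) × diag_months
                  = 3,627.6 × 0.10 × 0.9199 ≈ 333.7  →  334,

which the tree evaluation must match to 1e-6 — the model's principal internal
oracle.

## Accounting conventions (and why they are explicit switches)

The published strategy totals this model is calibrated against cannot be
reproduced from the published inputs under every natural accounting; the
conventions below are therefore explicit, configurable, and chosen as the
unique combination that reproduces all four published totals at once.

* **Diagnostic-window pricing** (`costs.diagnostic_pricing`). Under the
  default `published` accounting the standard-of-care arm carries the
  AAF-priced diagnostic exposure for the whole suspected cohort and the
  AAF-first arm's window is costed at the eHF price — the delayed-definitive-
  therapy arm bears the premium-formula diagnostic cost. This is the only
  assignment under which the eHF-first arm is the costlier one, and it
  reproduces the reference per-arm cost totals (checked to within 5%) and the
  incremental cost (checked to within 1%). `as_fed` charges each arm the
  formula it actually dispenses during its own window; it yields the opposite sign for
  the incremental cost (the AAF-first diagnostic premium, 12,334 × 256 USD ×
  0.92 months ≈ 2.9 M USD, then outweighs the 0.5 M USD rescue cost), which
  is incompatible with the reference accounting. Both modes leave the effect
  delta untouched.
* **Additive rescue.** The rescue window is charged on top of an age-anchored
  maintenance window (entry + one diagnostic window to exit age) rather than
  displacing it. Combined with `published` pricing this gives the incremental
  cost its closed form: cohort × price gap × window + non-responders × AAF
  price × window.
* **Entry age** (`time.entry_age_months`, default 3). Only "under 6 months"
  is specified by the setting; mid-interval entry at 3 months makes the
  per-confirmed-child symptom-free expectation 0.56 × 9 + 0.44 × 21 = 14.28
  months, matching the reference effect totals (checked to within 5%).
* **Week→month conversion** (`time.days_per_month`, default 365.25/12 =
  30.4375). The 4-week window is then 0.9199 months; a 1.0-month reading
  would overstate the effect delta by 9%.
* **Price-band switch** (`costs.age_band_switch_months`, default 9): the age
  at which the cheaper "older infant" monthly price applies, consistent with
  the 50%-formula-share assumption at 9 months; configurable to 12.

## Parameters

All base values live in `src/cmpa_cea/data/base_case.yaml` and are validated
on load (proportions in [0, 1], EBF + mixed ≤ 1, confirmed ≤ suspected
incidence, non-decreasing tolerance, positive costs). "AAF ≥ eHF price" and
"AAF ≥ eHF effectiveness" hold at base but are deliberately *not* hard
constraints: one-way sensitivity legitimately crosses them (the AAF low price
1,140 sits below the eHF base 1,170 — the corner where dominance is tightest,
margin ≈ 40,000 USD).

Cohort rounding: the exclusively-breastfed count is truncated
(131,342 from 131,342.82) and the suspected count rounded half-up
(12,334 from 12,333.77) — the pair of rules consistent with the published
head-counts. Can counts round half-up (10.04 → 10, 5.58 → 6; floor or ceiling
each fail one case).

## Sensitivity analysis

`default_ranges` emits the canonical seven one-way ranges — four monthly
costs at ±20%, two tolerance probabilities at ±25%, and the suspected-cohort
size at 11,000/14,000 — using the reference table's printed endpoints
verbatim when the base matches (their printed rounding follows no single
rule) and the fractional rules otherwise. Entries are ranked by absolute
spread of the chosen incremental outcome (default: incremental cost).
Old-band costs and tolerance probabilities produce zero spread on the
incremental outcomes: maintenance is identical across arms, so their effects
cancel — they do move per-arm totals. `stress_corner` additionally evaluates
the joint all-AAF-high/all-eHF-low price corner.

## Synthetic scenarios

`scenarios.draw` samples parameter sets with the base case's structure:
probabilities from beta distributions (mean = base value, pseudo-sample-size
`prob_concentration`, default 100 — roughly the precision of a 100-patient
study), costs from gamma distributions (mean = base, CV `cost_cv`, default
0.10 — typical price dispersion across procurement channels). The
confirmation probability is drawn conditionally on the suspected incidence,
and the tolerance pair is sorted after drawing, so every draw passes full
validation by construction (the sort's small bias is acceptable for a test
utility). The generator emulates parameter uncertainty only: it does not
model correlation between prices, IgE/non-IgE tolerance differences,
indirect or comorbidity costs, or sampling noise in the cohort counts — so
passing fuzz tests demonstrates numerical robustness of the pipeline, not
real-world validity of any single draw.

## Problem sizes and determinism

Everything is closed-form expectation arithmetic on one cohort; a full
pipeline run (both arms, 7×2 sensitivity re-evaluations) takes well under a
second, and the test suite's heaviest pieces are 1,000 random-tree
engine-oracle checks and 2,500 scenario draws. Reports are byte-stable when
the timestamp is suppressed; all randomness flows through a single seeded
generator.

## Limitations

* The 24-month horizon, single entry age and two-point tolerance schedule
  are coarse; no discounting is applied (sub-2-year horizon).
* Direct formula costs only: physician visits, out-of-pocket and
  comorbidity costs are out of scope by design.
* Deterministic cohort expectations — no microsimulation, no probabilistic
  sensitivity analysis in the headline surface (the scenario generator
  supports exploratory Monte-Carlo).
* The `published` pricing convention is a calibration choice, documented
  rather than derivable from first principles; `as_fed` is provided for
  analysts who prefer the literal dispensing interpretation.
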