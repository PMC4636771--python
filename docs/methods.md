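# Methods

## Scope and perspective

The package models a single year of conventional Pap-smear screening for
the HIV-infected subpopulation of a national programme, from the provider
perspective, in 2014 USD.  Costs and outcomes stop at the screening
encounter: no colposcopy, treatment, patient-tracing or patient-side costs,
no disease progression/regression between screens, no HIV-negative cohort,
and no HPV-testing arm.  Atypical glandular cells (≈ 0.1 % of reports) are
not modelled.  The decision is device choice — wooden elongated-tip
spatula vs plastic Cervex-Brush — under two practice variants that differ
only in what triggers a repeat smear.

## Inputs

Every input is a `ParameterSpec` in the packaged YAML registry:
19 epidemiological/flow parameters (normal- or proportion-distributed,
each with mean and 95 % interval bounds) and 5 point-valued cost
parameters.  Key values: annual screening volume 723,829 (95 % interval
583,056–869,393); HIV-positive fraction 51 % (40–64); true abnormality
73 % of smears in HIV-infected women, split HSIL 31 %, LSIL 37 %, ASC-US
5 %; endocervical-cell presence 53 % (spatula) vs 83 % (broom); cytology
sensitivity 76 % with endocervical cells, 40 % without (32 % for HSIL
without); specificity 84 %; smears satisfactory for evaluation 98 %; of
recalled women 92 % return and 90 % of returners receive the repeat;
visit $8.36, laboratory test $4.89, spatula $0.02, broom $0.22.

Semantics and conventions:

* Interval columns are read as central 95 % bounds (2.5th/97.5th
  percentiles, divisor 2 × 1.959964); a `p5p95` switch reinterprets them
  as 5th/95th percentiles (divisor 2 × 1.644854) since the source table's
  column labels admit either reading.
* Proportions are sampled as symmetric normal shapes matched to mean and
  bounds, truncated to [0, 1] — the printed intervals are symmetric about
  their means, which a beta generally is not; a moment-matched beta is
  available behind `proportion_dist="beta"`.  Normal-family parameters
  (counts, odds ratios) are truncated at zero.
* The annual HIV-infected cohort is computed per trial as volume × HIV
  fraction (369,153 at the means).  The registry also carries the
  source's pre-computed cohort figure (372,340, ≈ 0.9 % larger) for
  reference; it is not used by the tree.
* The odds ratios in the registry (broom adequacy effect 1.57, detection
  with vs without endocervical cells 1.89, severe-grade 2.46) are carried
  as documented inputs and exposed through the `or_apply` utility, but
  the default tree uses the registry's pre-computed probabilities
  directly: applying the printed odds ratios to the printed base rates
  does not reproduce the printed derived rates (1.57 on 53 % gives ≈ 64 %,
  not 83 %), so the published derivation is treated as external.
* The broom is costed at the tabulated $0.22 (a quotation source also
  cites $0.23; the cost table is taken as the input of record).

## Tree structure

Per smear, endocervical presence (device-specific) and satisfactoriness
(98 %) are independent draws; repeat smears draw both independently of
earlier rounds.  An unsatisfactory smear is unreadable and always recalls.
On a satisfactory smear, detected abnormalities are always reported,
with or without endocervical cells (grade-split sensitivity without).
A negative report lacking endocervical cells recalls under guidelines
practice and is final under typical practice.  A recalled woman receives
the repeat with probability q = 0.92 × 0.90 = 0.828 and is otherwise lost
to care without a diagnosis.  False-positive women exit at referral; the
loop cannot re-capture them.

**Loop depth.**  The recall loop is capped at `max_rounds` smears per
woman; women still recalled after the last permitted smear are counted
lost to care.  The default is `max_rounds = 2` (one repeat).  This was an
open structural choice — the practice rules alone do not bound the loop —
and was fixed by audit against the published programme-level results:
at the parameter means the depth-2 guidelines tree gives 1.280 expected
smears/woman and $16.98 per woman screened against the published $16.79,
and an incremental HSIL yield of ≈ 6,200 against the published 6,180,
whereas iterating to absorption gives 1.392 smears/woman ($18.47) and, by
granting the inadequacy-prone spatula unlimited second chances, a
*negative* incremental abnormal yield.  Any depth, and full absorption,
remain available via `max_rounds` (geometric closed forms throughout; the
unbounded variant guards against a non-contracting loop).

**Detection accounting.**  `detected_abnormal_total` counts true
positives; `include_false_positives=True` adds false-positive referrals.
The published results are not uniform here — the guidelines rows
back-calculate to true positives only, the typical-practice absolute row
to true plus false positives — so the package defaults to the reading
consistent with the guidelines tables and exposes the flag.  The
incremental typical-practice results are identical under both readings
(the false-positive terms cancel between arms).

Known residual discrepancies at the defaults, left as honest model
disagreement rather than calibrated away: the guidelines incremental
abnormal-detection total computes to ≈ 11,100 vs the published 14,222
(the published figure is consistent with applying the HSIL-specific
no-endocervical sensitivity to all grades, contradicting the input
table), and the guidelines lost-to-care reduction computes to ≈ 42,600 vs
the published 30,837 (no loop depth between 2 and absorption reproduces
it jointly with the cost rows).

## Economics

Every smear taken consumes exactly one outpatient visit, one laboratory
test and one device; a woman who returns but receives no repeat smear
incurs no cost.  `cost_per_hsil_detected` is programme cost over detected
HSIL (NaN marker when zero).  The incremental per-HSIL saving is the
difference of the two arms' ratios — matching the published arithmetic —
while `icer()` provides Δcost/ΔHSIL separately.  Dominance =
cheaper *and* more HSIL detected.

## Monte Carlo PSA

10,000 trials by default; each trial draws one parameter set shared by
both devices (common random numbers), so incremental intervals reflect
only between-arm differences — required to obtain intervals as narrow as
published.  Draws are inverse-CDF transforms of per-trial uniform streams
keyed by `(seed, trial)`, making the vectorized engine bit-identical to
trial-by-trial sampling and fully reproducible.  Summaries report the
mean with a 95 % CI **of the mean** (mean ± 1.959964·sd/√n; the published
interval widths match this construction, not percentile intervals), with
empirical 2.5/97.5 percentile intervals available via `interval_mode`.
Trials in which either arm detects zero HSIL are excluded from ratio
metrics and counted (none occur under the default registry's support).

## Synthetic cohort generator

`simulate_cohort` pushes women one at a time through the identical branch
rules — true grade from the grade mix, per-smear endocervical/satisfactory
draws, reported result, recall/return/repeat/loss — and emits one
laboratory-style record per smear (woman id, round, true grade, adequacy
fields, reported result, disposition).  It emulates the structure of
registry extracts (per-slide adequacy, endocervical presence, HIV status,
result); it does **not** emulate calendar time, clinic-level clustering,
within-woman correlation of repeat adequacy, or measurement error in the
recorded fields — so oracle agreement validates the expectation algebra,
not the realism of those aspects.  Tallying records reproduces every
tree expectation within 4 binomial standard errors at 10⁶ women (the
suite's core check, ~3 s vectorized), and a second, independently
hand-coded per-woman sampler in the test suite cross-checks the branch
rules themselves on a small fixed scenario, separating
"expectation-algebra bug" from "shared branch-probability bug".
Parameter-recovery tests invert the generator's per-smear proportions
within binomial error.

## Numerical choices

* Closed-form geometric sums everywhere; no iterative expectation loops.
  Terminal probabilities per true state are asserted to sum to 1 within
  1e−9 before scaling.
* Expected counts are real-valued; rendering rounds currency to cents,
  counts to integers, percent changes to whole percents.
* Oracle tests use n = 10⁶ women and 4-SE tolerances (false-failure
  probability ≪ 1 % across the asserted fields); PSA convergence tests
  compare 2,500- vs 10,000-trial CI widths (ratio 2.0 ± 0.15).
* Problem sizes in the suite (10⁶-woman simulations, 10,000-trial PSAs)
  are the package's standard validation scale and run in seconds.

## Limitations

Beyond the scope exclusions above: the model treats sensitivity,
specificity and adequacy as woman-independent (facility-level data offer
no covariates); repeat-smear adequacy independence is an assumption, and
positive correlation would erode the broom's guidelines-practice savings;
the cost per HSIL detected is conditional on the screening encounter only
— downstream colposcopy capacity needed by higher detection is uncosted;
and the guidelines-practice loop depth is a structural assumption fixed
by audit (see above), not an observed quantity.
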