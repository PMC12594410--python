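# Methods

## Problem and model

Two population-overlapping data sources describe the same cancer patients
without a shared identifier: a clinical registry (at most one observation per
linkage variable per patient — one consent visit, one 3-year follow-up, one
surgery episode with discharge, treatment-line start/end dates, month/year of
birth and death) and a claims extract (multi-valued event sets: every
in-hospital visit or stay with its establishment code, every
chemotherapy/radiotherapy session date, 2015-2020 observation window).

Linkage is deterministic and stepwise. A candidate pair's *score* is the
number of linkage variables on which the two records agree; each variable
contributes at most one point no matter how many underlying events match.
A variable with a missing observation on either side contributes nothing —
it neither matches nor disqualifies. The only imputation anywhere is the
explicit, flagged day-01 fill-in for month-precision dates used by downstream
consumers; the comparators themselves never invent precision.

### Dates with precision

`PartialDate` stores year / year-month / full dates explicitly. Two dates
match at granularity *g* iff both can be truncated to *g* and are equal
there; a precision shortfall is a non-match, not an error. This gives
coarsening monotonicity (a day match implies a month match implies a year
match), which the protocol's "adjusted" comparisons rely on: an adjusted
match is one achieved only at a granularity coarser than the variable's base
(MM/YYYY for event dates, YYYY for birth).

### Gates, strata, pools

In part 1 (substeps 1, 1.A, 1.B, 2, 3, 4) sex and month/year of birth must
agree before a pair is scored; gate variables also count toward the score,
which is the only reading under which "score >= 4" is attainable at substeps
whose step-specific list holds three variables, and under which "3 variables
with at least two matching session dates" differs from the plain threshold.
Stratification keys are presence/absence indicators computable on both
sides: (has surgery data, has death date) for step 1 — surgery data meaning
any surgery/discharge event or any set flag in the surgery-type triple —
then sex x has-chemo, sex x has-radio, has-endoscopy. A record whose registry
side lost its surgery data lands in a different stratum from its claims twin
and is deliberately *not* matched in part 1; the unstratified part-2 steps
exist to catch exactly these.

Claims candidates must have at least one in-hospital contact. Part 1
restricts the pool to patients with an outpatient *visit* event; part 2
expands it to any visit or stay.

### Acceptance rules and the adjusted-match cap

Acceptance is `MIN_SCORE(4)` (substeps 1, 1.A, 1.B, 4), `MIN_SCORE(4)` or
3-with-two-session-dates (substeps 2-3), or exact scores 9/7/6 (step 7's
three rows). The "Score >= 4" vs "Score >= 4 (including 1 adjusted
variable)" row pairs of steps 5 and 6 are implemented as sequential substeps
sharing one scorer but differing in an integer cap on counted adjusted
matches: the strict substep counts only exact-granularity matches
(`max_adjusted = 0`), the relaxed one lets a single adjusted match count
(`max_adjusted = 1`). Under this reading substeps 5-strict and 6-strict
apply the same predicate; 6-strict is still productive because every earlier
substep removes linked records from both pools, so a candidate that was
ambiguous earlier can become unique. This pool-shrinkage mechanism is the
package's resolution of the otherwise puzzling fact that re-running a
near-identical rule yields new links, and it falls straight out of the
uniqueness rule below.

### One-to-one uniqueness

After all in-step pairs are scored, the accepted pairs form a bipartite
graph; a pair links iff both endpoints have degree 1. Everything else is
logged as an ambiguity and stays eligible for later steps. Resolving
uniqueness globally after scoring (never greedily in input order) makes the
engine's output invariant under row permutation — a property the tests
assert — and hence byte-deterministic. The candidate index on (stratum, gate
key) is a pure equality prefilter; an exhaustive all-pairs oracle in the test
suite confirms on randomized instances that it never changes results.

## Preprocessing

Before linking: observations dated after 2020 are recoded missing (follow-up,
surgery, discharge, endoscopy) or filtered (chemo/radio sessions); birth and
death dates are truncated to month/year; claims-side treatment variables are
restricted to the 2015-2020 window. All of these are pure functions of a
record and idempotent.

## Synthetic cohorts

The generator draws one care pathway per patient — index date uniform over
the 2015-2019 selection window, age normal(63.8, 12.5) clipped to 25-94,
male fraction 0.764, home facility among 42 centres, consent visit at index,
follow-up at consent + 3 years (often spilling past 2020 and thus recoded
missing, as in real data), surgery in 73% with 3-15 day stays, chemotherapy
in 86% (1 + Poisson(8) sessions), radiotherapy in 19%, endoscopy in 2%,
death in 35% censored at the window end — and renders it twice: a claims
view kept faithful (plus Poisson(3) unrelated visits tagged visit/stay), and
a registry view degraded at configurable rates (default 10% per-variable
missingness, 5% date-entry errors of up to ±7 days, 2% facility swaps, and
birth-month slips that exercise the year-granularity gate). The registry
stores only each treatment line's start/end dates while claims hold every
session, which is what makes the "at least two matching dates" rule
meaningful. Degradation targets the registry side because that is where
entry errors predominantly arise in this setting.

All draws come from one seeded NumPy generator in a fixed order, so a config
plus seed reproduces a cohort exactly. The default cohort size is 1617
registry patients with 90% claims overlap and 3000 claims-only patients.

What the generator does *not* emulate: clinically plausible visit sequences,
claim costs, diagnosis codes, regional facility structure, or correlated
missingness. Passing tests therefore demonstrate the engine's correctness
and its behaviour under independent, well-specified noise — not the linkage
rate to expect on any real registry.

## Statistics

Linkage quality against ground truth is sensitivity (true pairs recovered),
PPV (links that are true; undefined with zero links) and F1.
Representativeness of the linked subpopulation compares linked and
non-linked patients per covariate: Pearson chi-square without continuity
correction (p from the chi-square(1) upper tail, `erfc(sqrt(X/2))`) for
categorical covariates, switching to the Fisher exact test when any expected
cell is below 5 — the conventional rule, adopted here because the decision
threshold is otherwise unspecified — and the pooled two-sample t-test for
continuous ones. Omitting the continuity correction is deliberate: it is
what reproduces the published p-values from the published counts. Fisher's
two-sided p uses the probability-mass rule (summing hypergeometric
probabilities no larger than the observed table's, with 1e-7 relative
tolerance on the comparison), matching standard reference implementations.
Cumulative step percentages are rounded half-up to one decimal.

## Numerical and design choices

* Facility codes compare by exact string equality after trimming and
  uppercasing; they are administrative identifiers, not free text.
* Death dates compare at month granularity on both sides; a present-vs-
  missing death is a non-match but not disqualifying.
* Session-date distinctness is counted after coarsening, so two sessions in
  one month count once at month granularity.
* Step 7 thresholds are exact (9, then 7, then 6, in that order); a pair
  scoring 8 does not link. The maximum attainable step-7 score is 10
  (variables 1-7 and 9-11).
* Surgery-type triple (variable 8) and department of residence (variable 12)
  are parsed, compared and available to custom protocols, but the canonical
  protocol scores neither: variable 8 drives step-1 blocking, variable 12 is
  an optional comparator left disabled.
* Records missing a stratification attribute are excluded from that step
  rather than broadcast into every block; the unstratified steps recover
  them.
* Problem sizes: the acceptance script's end-to-end synthetic run uses 400
  registry patients (other generator defaults unchanged), enough for stable
  quality estimates at desk scale; tests use 25-150 patients per instance.

## Known limitations

* The adjusted-match cap semantics for steps 5-6 and the exact blocking keys
  are the package's own resolution of ambiguities in the published protocol
  description; alternatives (e.g. treating coarse variants as separately
  scored variables) would change step-level counts but not the one-to-one
  guarantees.
* The engine is quadratic within (stratum, gate) groups; step 7, having no
  gate, compares all remaining pairs. Fine for cohorts of a few thousand,
  not tuned for millions.
* No probabilistic (Fellegi-Sunter) scoring, no clerical-review queue, no
  manual verification workflow.
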