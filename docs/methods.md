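# Methods

## Problem and model

Chronic dialysis for end-stage renal disease (ESRD) is delivered almost
entirely in the outpatient setting, so outpatient physician billing claims
are a natural source for identifying chronic dialysis patients when no
registry is accessible. `dialclaims` implements four temporal case
definitions over a patient's dated outpatient dialysis claims, and the
agreement framework used to validate them against a registry reference
standard.

A patient's input is reduced to a *claim-day series*: the strictly
increasing sequence of distinct calendar days on which the patient has at
least one outpatient claim carrying a dialysis procedure code (the six CCP
codes 13.99A/B/C/D/O/OA) inside a closed observation window. The four
definitions, in order of increasing stringency:

| id | rule |
|----|------|
| d1 | ≥ 1 claim day |
| d2 | ≥ 2 claim days |
| d3 | ≥ 2 claim days at least 90 days apart (max − min ≥ 90) |
| d4 | some run of claim days with every successive gap ≤ 21 days spanning ≥ 90 days |

These are nested: d4 ⇒ d3 ⇒ d2 ⇒ d1. A d4-positive series necessarily has
at least ⌈90/21⌉ + 1 = 6 claim days. The cohort-entry **index date** is the
second distinct claim day; a single-claim d1 positive enters on its only
claim day (the second-claim rule presumes two claims and gives no
alternative, so the first claim is the only defensible fallback).

### Counting conventions

* Claims are counted as distinct claim *days*: two billings on one day
  (e.g. a resubmission, or two physicians) cannot manufacture chronicity
  and do not satisfy d2.
* "At least 90 days apart" is inclusive (≥ 90); "gap greater than 21 days"
  is strict (a gap of exactly 21 days does not break a run). Differences
  are exact calendar-day counts, no month approximation.
* d3 uses the extreme dates only (equivalent to scanning all pairs, O(1)).
* d4 accepts *any* qualifying run, not only one anchored at the first
  claim; the detector is a single linear scan over maximal ≤21-day-gap
  runs and is property-tested against brute-force enumeration of all
  contiguous sub-runs.
* Per-week management codes (13.99O, 13.99OA) are treated as point events
  on their service date, not as 7-day coverage intervals: expanding them
  into covered days would silently change the 21-day gap semantics.

## Agreement statistics

Against a registry reference standard, each definition yields a 2×2 table
(a = both positive, b = claims only, c = registry only, d = neither;
N = a+b+c+d). Reported per definition: sensitivity a/(a+c), PPV a/(a+b),
Cicchetti–Feinstein positive agreement 2a/(2a+b+c), Cohen's kappa
(p_o − p_e)/(1 − p_e) with p_o = (a+d)/N and
p_e = [(a+b)(a+c) + (c+d)(b+d)]/N², and claims prevalence 100(a+b)/N.

Positive agreement is deliberately implemented as 2a/(2a+b+c) — the
chance-uncorrected agreement restricted to positive classifications —
because that formula reproduces the published validation table, and
because it is the rare-outcome limit of kappa: with a, b, c fixed and
d → ∞, p_o → 1 − (b+c)/N and p_e → 1 − (2a+b+c)/N + O(N⁻²), so
κ → 2a/(2a+b+c). At N ≈ 1.1 million and ~2,200 cases the two agree to
< 10⁻³, which is why published tables for rare outcomes print identical
kappa and positive-agreement columns.

Specificity, NPV, and negative agreement are computable
(`include_negative=True`) but excluded from default reports: with ~10⁶
true negatives they sit at ≈ 1.000 under every definition and carry no
information about the case definition.

Kappa bands follow Landis–Koch with half-open intervals: ≤ 0.20 poor,
(0.20, 0.40] fair, (0.40, 0.60] moderate, (0.60, 0.80] substantial,
> 0.80 near-perfect (the conventional quoted bands leave (0.80, 0.81)
unassigned; 0.80 is classified substantial here).

Statistics are carried at full precision; rounding — half-up, three
decimals for proportions and kappa, two for prevalence percentages —
happens only at serialization. Two cells of the published table are
half-ulp rounding edges (1406/1657 = 0.84852 vs printed 0.848;
1295/2227 = 0.58150 vs printed 0.582); the package reports the exact
values, which agree with the printed ones within 10⁻³.

## Study population and the d cell

The validation study's N came from a laboratory cohort (everyone with an
outpatient serum creatinine), which cannot be reconstructed from claims
and registry files. By default the population is every patient id seen in
any input, so d — and with it kappa and prevalence — depends on the inputs
supplied. `population` (explicit ids) or `population_size` (total N,
padding d with anonymous true negatives) pins N exactly; this is how the
published kappa of 0.793 is reproduced from the published membership
counts at N = 1,118,097. A registry record counts as a reference-standard
positive when its start date is on or before the window end.

## Synthetic data generator

`simulate(SimScenario(...))` emulates the billing processes that the
validation's error taxonomy identifies, with ground-truth labels:

* **Chronic (registry) patients** (`registry_prevalence`, default 0.002 —
  the observed registry prevalence in a creatinine-tested adult
  population). A fraction `prevalent_fraction` (default 0.75; ESRD point
  prevalence is several times annual incidence) are already on dialysis at
  window start with a registry start date back to 1999; the rest start
  uniformly during the window. Hemodialysis patients (`hd_fraction`,
  default 0.8, the typical HD/PD split) bill the per-week management code
  every 7 days; peritoneal-dialysis patients bill the monthly assessment
  code every 30 days. A per-session mode (13.99B every ~3 days) is
  available.
* **Billing noise**: each due claim is actually captured with probability
  `claim_capture_prob` (default 0.95) — missed billings, billing errors,
  and shadow billing by salaried physicians all present as dropped claims.
* **Early death**: a geometric per-day hazard (`early_death_hazard`,
  default 0.001/day ≈ 30%/year, realistic dialysis mortality) truncates
  the claim stream; no claims are emitted on or after the death date.
  For incident patients the clock runs from dialysis start; for prevalent
  patients it runs from window start, since being prevalent *means* being
  alive on dialysis at window start and the geometric hazard is
  memoryless.
* **Temporary (AKI) dialysis** (`aki_rate`, default 0.0005 — the order of
  the false-positive excess observed in the validation): a burst of
  unstable-hemodialysis claims every 3 days, with gamma-distributed
  episode duration (mean 30 days, shape 1.5) truncated to [1, 89] days, so
  temporary dialysis can never satisfy the 90-day rules by construction.
  Duration-1 episodes double as stray single-claim billing errors.

Same seed ⇒ byte-identical output files; all randomness flows from one
`numpy` generator.

### What the generator does and does not emulate

It reproduces the *qualitative* error structure: temporary dialysis
dilutes the PPV of permissive definitions and is removed by the 90-day
rules; missed billings erode the continuous definition's sensitivity
fastest; early death creates registry positives with few or no claims.
It does **not** attempt to calibrate the absolute published statistics —
those depend on unobservable real-world noise rates — and it simplifies
real billing: per-week codes are emitted on a strict 7-day lattice (real
billing is irregular around holidays and hospitalizations), monthly PD
billing makes PD patients structurally d4-negative (real PD patients
accrue additional dialysis-related claims), and comorbidities are not
simulated. Passing tests therefore demonstrate correctness of the
algorithms and the direction of noise effects, not the real-data values
of sensitivity or PPV.

## Numerical and degenerate-input choices

* Dates are ISO-8601; the window is closed at both ends.
* Duplicate registry rows keep the earliest start date (with a warning).
* Statistics with empty denominators raise `UndefinedStatisticError` at
  the function level; the pipeline report records them as NaN so that a
  run with, say, zero claims still produces a report row (sensitivity 0,
  prevalence 0%, PPV undefined).
* Everything downstream of input order is sorted; reports are
  byte-reproducible.

## Problem sizes used in the shipped checks

The verification suite uses: exhaustive-oracle comparison on 10,000
random series of ≤ 12 claim days; nesting on 1,000 small randomly
parameterized cohorts; noise-free recovery at n = 50,000; and
directional noise comparisons as means over 20 seeded replicates at
n = 20,000 — sizes at which the binomial noise on the compared means is
far smaller than the effects being asserted.
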