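# Methods

## The phenotyping problem

Coded EMR data record *evidence* of exacerbations, not exacerbations
themselves. A single clinical episode may generate several records across
channels (an exacerbation code, an LRTI code, symptom codes with same-day
prescriptions, a hospital episode), may be recorded twice a few days apart,
or may be written retrospectively at an annual-review visit; conversely a
short oral corticosteroid course can reflect an entirely different illness.
Each of the six algorithms is a different trade-off between these error
modes. The package treats an **event as a patient-day**: all candidate
records on one day merge into one event whose provenance lists every
detector that fired, and the event is *severe* if any hospital/A&E detector
fired that day.

## Day-level rules

All date arithmetic is in whole days (ISO dates at day resolution).
Primary-care codes are matched by exact string membership in a codelist
category; the coding system is otherwise opaque. ICD-10 codes are matched on
their undotted 4-character form (`J44.1` ≡ `J441`), since hospital extracts
store undotted codes.

* *Symptom conjunction*: ≥ 2 distinct categories among {chronic cough,
  breathlessness, sputum} coded on the same day as ≥ 1 respiratory
  antibiotic **and** ≥ 1 OCS prescribed for 5–14 days (inclusive).
* *Missing prescription duration fails any duration criterion.* Duration is
  never imputed at the I/O layer; the conservative default can be revisited
  by widening `ocs_duration_range`. (Duration fields in real extracts have
  high missingness, which is itself a sensitivity-reducing mechanism the
  simulator reproduces via `p_duration_missing`.)
* *Hospital rule*: J44.1 or J44.0 in any diagnosis position, J44.9 only as
  the primary diagnosis.
* *Annual-review exclusion* drops **moderate** events dated on a day with an
  annual-review code; hospital/A&E-sourced events are exempt, because the
  artifact the rule targets — retrospective primary-care coding at a review
  visit — cannot produce an admission record.
* *14-day deduplication* is a greedy forward scan per patient: the earliest
  event is always retained; a later event is retained iff its gap from the
  last **retained** event is strictly greater than the window (a gap of
  exactly 14 days counts as "within 14 days" and is dropped). The scan is
  idempotent and runs across the moderate/severe boundary (one event stream
  per patient). Review exclusion runs **before** deduplication so a
  review-day artifact cannot suppress a genuine nearby event by acting as a
  dedup anchor.

The filter pipeline runs on each patient's full in-span record stream
(registration start to follow-up end) and any observation window (e.g. the
baseline year) is applied afterwards, so windowing never changes which
events anchor the dedup chain.

## Cohort construction

Index date = max(first COPD code date, 40th birthday, registration start +
365 days, study start, day after first consultation). "Over the age of 40"
is read as age ≥ 40 at index; "consultation prior to index" is strict,
baseline condition lookups are inclusive of the index day. Follow-up ends at
the earliest of 2019-12-30, death, or deregistration. Attrition is reported
in a fixed order (COPD code → age → smoking → linkage → registration ≥ 1 y →
prior consultation → positive follow-up), each patient counted under its
first failed criterion, so exclusions plus the final cohort always sum to
the input count. Smoking status at index is the most recent smoking-status
record on or before index, with same-day ties resolved current > ex > never.
Age at index is whole days from birth divided by 365.25.

## Synthetic EMR model

True events per patient follow a homogeneous Poisson process with intensity

```
λ_i = λ0 · frailty_i · exp(β_HF · HF_i)
```

over the window from one year before index to follow-up end (so the
baseline year is populated). Defaults: λ0 = 1.2/year — a plausible COPD
exacerbation rate given that roughly half of patients exacerbate in a year;
frailty variance θ = 0 (gamma frailty with mean 1 when positive, giving
negative-binomial marginal counts); β_HF = ln 1.5 — a moderate, detectable
hazard ratio for baseline heart failure; 10% of events hospitalised.
Demographics default to a COPD-like cohort: mean age 68 (SD 10), 47% male,
46% current smokers, 10% baseline heart failure.

Each **moderate** true event independently emits, per channel: an
exacerbation code (0.45), an LRTI code (0.15), a symptom pair/triad with a
same-day antibiotic and OCS (0.10; OCS duration uniform on 5–14 days,
missing with probability 0.20), and an OCS-only prescription (0.20); a
recorded exacerbation code is duplicated at a 1–10-day lag with probability
0.20. **Severe** events always emit a hospital episode (J44.1/J44.0 at a
random position 1–3, or J44.9 primary, with unrelated filler diagnoses) and
an A&E attendance with probability 0.60; they emit no primary-care records.
Annual reviews occur on index anniversaries; each true moderate event of
the preceding year is retro-coded on the review date with probability 0.15.
Background OCS (0.15/patient-year) and LRTI (0.10/patient-year) records are
independent Poisson noise; 3% of patients have an A&E respiratory attendance
with no admission, 1% an asthma-coded attendance. The channel probabilities
are illustrative, chosen so the validated-style algorithm's event-level
sensitivity lands near the ~0.6 reported for GP-recorded exacerbations in
published validation work, with PPV near 0.85; no quantitative claim about
any real database is intended or possible from them.

Per-year multipliers can scale the channel probabilities
(`calendar_drift`) or, separately, the retrospective review-coding
probability (`retro_calendar_drift`). The drifts act only on the coding
layer; the true process is always calendar-stationary, which is what makes
the secular-trend artifact identifiable.

Determinism: each patient draws from an independent substream keyed by
(seed, patient index), so patient k's records do not depend on the cohort
size and any seed yields a byte-reproducible bundle.

Scenario presets: `validated-mix` (defaults above), `perfect-coding` (one
channel with probability 1, nothing else — detected events equal true
events), `high-fidelity` (0.9 single-channel sensitivity, no noise, 5-year
window — thinning a Poisson process preserves proportional hazards, so the
heart-failure HR is recoverable), `review-inflation` (retro coding ramping
from ×0.05 to ×1.0 across 2010–2019), `ocs-noise` (2 background OCS
scripts/patient-year, diluting the OCS-only algorithm's association), and
`gold-like` (an alternative coding mix emulating a database whose recording
software favours different channels).

What the generator does **not** emulate: seasonality and pandemic shocks,
informative censoring, death driven by the event process, free text,
miscoded patient identity, and within-practice clustering. Passing tests
therefore show the algorithms and analyses behave correctly under the
modelled mechanisms — not that any particular real-world database shares
those parameter values.

## Statistical conventions

* Index-anchored "years" (baseline window, follow-up year k) are 365 days;
  person-years use 365.25 days; person-months use 30.44 days.
* Follow-up person-time is the half-open interval [index, follow-up end);
  calendar-year splitting cuts it at 1 January boundaries, so the yearly
  person-time sums exactly to the total. Events are counted on [index,
  follow-up end] inclusive and assigned to the calendar year of their date.
* Rate CIs are exact (chi-square/Poisson) below 100 events and log-normal
  above; the threshold is configurable and exists purely for speed.
* The frequent-exacerbator denominator for follow-up year k is members whose
  follow-up covers the whole year (active follow-up).
* Cox models use lifelines' partial likelihood with Efron tie handling,
  covariates: heart failure (binary exposure), age (continuous), sex,
  smoking (current vs ex). Patients whose first event falls on the index
  date have zero survival time — undefined in the partial likelihood — and
  are excluded from the risk set. Death is censoring only. Fits with zero
  events or a constant covariate raise a diagnosed error rather than
  returning output.
* Event matching against ground truth is greedy, earliest-first, one-to-one
  within ± a day tolerance — deterministic, order-independent given sorted
  inputs, and exact at tolerance 0; optimal bipartite matching would differ
  only at positive tolerances and is noted as an extension. Cohen's κ uses
  the standard marginal-expected-agreement form; when expected agreement is
  1, κ is defined as 1 for identical classifications and NaN otherwise.
* A&E-to-admission linkage window defaults to 1 day (attendance day or the
  next); "corresponding admission" has no canonical timing and the window is
  a flag.

## Design choices that were genuinely open

* Whether deduplication crosses the moderate/severe boundary: yes (single
  event stream), since the downstream analyses pool severities.
* Whether "within 14 days" includes day 14: yes (inclusive boundary).
* Whether the annual-review exclusion applies to severe events: no (exempt).
* Frequent-exacerbator counting for algorithms 3–5 uses their as-defined
  (unfiltered) event streams by default; both filter modes are exposed
  everywhere (`filter_mode` ∈ {as_defined, none, full}).
* Age is computed at index, not study entry; smoking history is required on
  or before index.
* Eligibility in the simulator is guaranteed by construction rather than
  rejection-sampled; a `p_ineligible` toggle injects violations so the
  attrition logic can be tested separately from the event process.

## Problem sizes

The shipped test-suite and acceptance-script runs use simulated cohorts of
300–20,000 patients (20,000 for hazard-ratio recovery; 100 replicates of
2,000 for null CI coverage; 10,000 randomly generated record grids for the
rule-equivalence check; 600–4,000 elsewhere). These sizes give Monte-Carlo
error comfortably inside the asserted bands while keeping a full run on one
CPU in minutes.

## Known limitations

* Codelists ship as illustrative synthetic sets; the engine is
  category-driven, so results on real data depend entirely on the
  user-supplied codelists.
* The simulator's per-channel independence is a simplification; real coding
  channels are correlated within a consultation.
* No recurrent-event survival models (the first-event Cox model is the
  target analysis); no proportional-hazards diagnostics; no competing-risk
  handling of death.
* With frailty θ > 0 the marginal first-event hazard ratio is attenuated
  relative to exp(β_HF); parameter-recovery checks therefore fix θ = 0 and
  frailty scenarios are exercised qualitatively only.
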