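# Methods

This note documents the models and procedures the package implements,
the parameters that matter, what the synthetic generator does and does
not emulate, and the design choices made where the rules left room.

## Data model and date arithmetic

All dates are parsed at the I/O boundary and carried internally as
integer day offsets from a fixed epoch (2000-01-01). Every rule in the
pipeline — washout, episode gap, regimen lock, grace period, eligibility
windows — is integer day arithmetic over half-open intervals
`[start, end)`. The half-open convention is applied uniformly: an event
on an episode's end date belongs to the next interval, a fill on a
regimen boundary to the new regimen, and durations are `end − start`
days.

ICD-9-CM codes are canonicalized to dotted form (dot inserted after the
3-character head, 4 for E-codes) and matched to configured groups by
string prefix, so a 4-digit group head such as `296.2` captures the
5-digit codes `296.20`–`296.26` that claims actually carry. Unknown drug
identifiers are retained but classed `OTHER_NON_ADAP`: they contribute
pharmacy utilization but never enter regimens. Validation never raises
on content; it returns issue records (orphan claims, unmapped drugs,
invalid days supply, reversed periods, claims before birth).

## Cohort selection

Filters are applied in cascade order: exclusion diagnosis (any
schizophrenia / schizoaffective / bipolar code at any time), then age,
then index-date confirmation. Windows are fixed in days: "4 months
prior" = 120 days, "24 months after" = 720 days, matching the 120-day
washout used for new-episode identification. Continuous eligibility
tolerates no gap; adjacent enrollment periods (next start = previous
end + 1) merge into one. The age filter (18–64 completed years) is
evaluated at the earliest washout-clean candidate index date, since the
cascade places age before eligibility confirmation; the final record
also re-checks age at the confirmed index date so the invariant
`included ⇒ 18 ≤ age ≤ 64` holds unconditionally. Patients whose only
candidates fail eligibility are excluded as `no_index_date`.

## Episode construction

Relevant events are inclusion diagnoses and antidepressant fills
(classes SSRI, SNRI, atypical antidepressant, other antidepressant,
MAOI — antipsychotics and lithium are regimen drugs but not episode
events, consistent with the washout's "antidepressant" wording). A gap
of exactly 120 days continues an episode; only a clear period longer
than 120 days ends it, after which the episode closes 120 days after
its last event, so every episode lasts ≥ 120 days. Episodes are built
from the index date forward; prescription events not chained to a
preceding inclusion diagnosis start nothing. Days-supply tails do not
extend the last relevant date: episode boundaries use claim dates only.

## Regimen engine

Per-drug validity: a fill at day *f* with supply *d* covers
`[f, f+d)`; a refill within the 60-day grace after the current validity
end extends validity continuously through the gap (to
`max(end, f+d)` — supply does not stockpile); a later refill opens a
new interval. Grace resolution precedes segmentation, so a validity end
is final by construction.

Segmentation walks each episode event-by-event:

* A regimen's composition is the union of drugs valid at any point in
  its first 30 days, **inclusive** of a fill landing exactly on day
  `start+30` (the locked interim ends after that day; the first
  re-check is the first fill date *strictly* after it).
* After the lock the regimen ends at the first date where the valid set
  differs from the composition: a new drug's fill date, or a member
  drug's validity end (drops occurring inside the lock surface at the
  lock's end). A drop with no addition produces a step-down regimen.
* When no member remains valid, a successor regimen commencing within
  30 days of the validity end extends the old regimen to its
  commencement; otherwise the regimen ends 30 days after its validity
  and a blank regimen spans the gap to the next commencement or the
  episode end.
* Regimens are truncated at the episode end and tile
  `[first validity start, episode end)`; with no ADAP fills the whole
  episode is one blank regimen.

These semantics guarantee that consecutive non-blank regimens differ in
drug set (the grace period prevents a dropped drug from reappearing
inside the next regimen's interim) and that only episode-end truncation
produces a non-blank regimen shorter than 30 days. The test suite
cross-checks the engine against an independent day-by-day simulator
that applies the same rules by brute force over explicit day sets.

Lines of therapy number the non-blank regimens in order. Blank regimens
do not increment the counter, and a non-blank regimen after a blank is
a new LOT even when its composition equals the pre-gap regimen. A blank
also breaks step-down adjacency: resumed therapy after a treatment gap
is not a taper of the pre-gap regimen.

## TRD classification

Every non-blank regimen is a failure (switch or discontinuation) except
(a) the last non-blank regimen of the episode — which also covers
therapy tapering out through the episode end via a trailing blank — and
(b) any composition ever immediately followed by a step-down, exempt in
**all** its instances. The composition-wide reading follows the rule's
"in all instances in which the regimen appeared" clause; an
instance-local variant (only the specific instance followed by the
step-down is exempt) is available behind
`assess_failures(..., composition_wide_exemption=False)`. A regimen
followed by a blank gap and then further treatment is a failure
(discontinuation). TRD requires ≥ 2 *distinct* failed drug-set
compositions — repeats count once, and the two failures need not be
consecutive. TRD onset is the start of the regimen whose commencement
confirms the second distinct composition as failed, because a failure
is only knowable at the switch or discontinuation that follows it.

## Outcomes and inference

Comparisons contrast TRD episodes with drug-treated (≥ 1 ADAP fill)
non-TRD episodes. Patient-level measures (sex, age bands 18–35 / 36–50
/ 51–64, comorbidities) use the distinct patients behind each episode
group; a patient with any TRD episode is a TRD patient. Class usage is
the share of group episode-days on which a class is part of the active
regimen (combination shares overlap). MRU attributes each claim to the
episode containing its date; per category, B = visits per 100
episode-days (ratio of sums), C = cost per visit, D = cost per episode,
so D = A·(B/100)·C holds exactly before rounding. Claims outside any
comparison episode accumulate in a residual bucket, preserving total
cost. Office visits split GP/FP vs psychiatrist through the claim
setting key; each claim row counts as one visit (inpatient stays are
not rolled up across claim lines). Psychotherapy sessions per episode
are reported as an additional category.

The TRD episode rate is `n_TRD / n_treated × 100`; the
duration-adjusted prevalence weights each group by episode-days
(count × mean duration). t-tests run from summary statistics with
pooled degrees of freedom or the Welch–Satterthwaite approximation; the
"auto" rule chooses pooled unless a preliminary folded F-test rejects
equal variances at 5% (the conventional companion to that dichotomy).
The proportion test uses the pooled standard error without continuity
correction. The Bonferroni cutoff is α/n; because the exact membership
of a 44-comparison family is report-specific, the report applies the
cutoff to all comparisons it emits and records the family size used
(overridable via `Params.bonferroni_n`).

## Synthetic generator

The generator emulates the statistical structure the analysis assumes:
per-patient diagnosis/fill streams with a 30-day-dominant days supply
(80% of fills), 68% female, a trajectory mix of 62% untreated episodes,
single-line responders, augment-then-step-down (`{X}→{X,Y}→{X}`)
non-TRD trajectories, and 3–5-line TRD-like trajectories in which each
line is terminated by a switch; second episodes for 15% of patients;
patients planted to fail each cohort filter; comorbidity claims at
group-specific patient-level rates and per-category utilization events
with lognormal costs of realistic magnitude. Refill gaps are bridgeable
by default; `breaking_gap_prob` deals gaps in the non-bridgeable range
(91–115 days, long enough to break the grace but not the episode),
which inserts a blank regimen and an extra line. The generator counts
every break it deals, so intended line counts and TRD flags remain
exact even in noisy scenarios; only the intended TRD onset can shift
earlier when a break lands inside a later line, and `expected_labels`
marks those episodes.

What it does **not** emulate: dose titration, adherence gaps shorter
than the grace period, cross-class switching preferences, seasonal or
calendar effects, inpatient claim-line structure, cost inflation, or
the headline frequencies of any particular real cohort (rates were
chosen for realistic magnitude, not calibration). Passing recovery
tests therefore demonstrates that the pipeline implements the rules
faithfully on data with the assumed structure — not that the rules
identify clinical treatment resistance in real claims.

## Numerical and scale choices

Deterministic throughout: generation is a single `numpy` PCG64 stream
per scenario seed; the pipeline itself draws no randomness and reruns
bit-identically. Test and acceptance runs use 400–2,000-patient
cohorts, 1,000 random fill sets for oracle equivalence, and 10,000
replicates for type-I-error calibration — sizes at which every check is
stable under the fixed seeds while the full suite stays fast. Zero
variance in both t-test groups with equal means yields p = 1 by
convention; zero denominators in rates are flagged and returned as NaN
(0 when the numerator is also 0).

## Known limitations

Episodes are built only from the index date forward; pre-index episodes
in longer histories are out of scope. The instance-local step-down
variant is implemented but not the default. The comorbidity code groups
shipped with the generator are illustrative configuration, not a
clinically validated mapping. Eligibility is ignored after index-date
confirmation, so late disenrollment can truncate observed (not
constructed) behaviour in real data.
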