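# Methods

## The recruitment protocol as a state machine

Every identified patient starts `OPEN`.  The protocol distinguishes four
staff steps — identification, eligibility review, contact, enrolment —
and the engine encodes them as events folded through a transition
function.  `EXCLUDED`, `REFUSED`, `ENROLLED` and `DECEASED` are
absorbing: once a record is finalized only further `epr_open` events are
legal (charts are still opened; no reminder fires).  Ignored reminders
(`click_off`) and consented-but-unfinished surveys
(`SURVEY_IN_PROGRESS`) remain open business: the reminder re-fires at
every subsequent chart opening until the process is finalized.

Replay enforces the rules that the pure transition function cannot see:
events are time-ordered per practice, the first event per study id is an
`epr_open`, any other event must follow an `epr_open` for the same record
on the same calendar day, refusal and consent require a prior contact,
and a survey can only start after consent.  Replay is deterministic, so
the registry is exactly the fold of the log — the property the real-time
study-centre registry relies on.

Age is evaluated at the date of each `epr_open`, not at study start, so a
patient crossing the 60/70-year threshold mid-study enters the net sample
at their next visit; this matches a tool that continuously monitors the
EPR user interface and picks up newly registered patients.

### Accounting conventions

* `identified = open + excluded + contacted` and
  `contacted = refused + enrolled` hold on every log by construction
  (they are validated whenever a `FunnelCounts` is built).
* Unfinished surveys are counted inside `open` with a separate sub-count;
  deceased EPRs are counted inside `excluded` with a separate sub-count.
  The published study funnel leaves no separate arm for its 22 deceased
  EPRs (its three top-level arms already sum to the identified total),
  and the exclusion arm is the conservative place for them.
* Table percentages are rounded half-up to one decimal; prose-style
  percentages half-up to integers.  Both the small/large threshold
  (600 identified EPRs) and the poor-recruiter cutoff (5% of own net
  sample) are parameters with the reference study's values as defaults.

## Pseudonymisation

Study ids are truncated HMAC-SHA256 digests (80 bits, base32) of the
practice-internal patient id under a per-practice secret.  This gives
determinism (the same patient maps to the same study id at every visit),
injectivity in practice (collision probability ~5e-13 across a
10,000-patient panel), and one-wayness: re-identification requires the
practice-side key map, which never leaves the practice.  The log schema
deliberately has no field for the internal id or full birth date.

## The reference dataset

The packaged fixture is the complete printed accounting of a 25-practice
German general-practice recruitment study (12 months, osteoporosis risk
survey, net sample women 60+ / men 70+): the study-wide funnel, the
per-practice enrolment table, and the stage × stratum demography table.
Stratum counts are integer reconstructions of the printed column
percentages by largest-remainder apportionment of each stage total;
every reconstructed count reproduces its printed share to one decimal.
One printed pair of cells — the men's "open"-column age split — is
arithmetically inconsistent with the net-sample column under funnel
conservation and appears row-transposed in print; the fixture stores the
conservation-consistent orientation (58.5% aged 70–79, 41.5% aged 80+).
The source also quotes a 98% survey-completion rate whose own counts
(1,526 of 1,569) give 97.3%; the package reports the recomputed value.

`reference_event_log()` expands the counts into a synthetic event log:
one minimal legal event sequence per patient, dealt round-robin across
practices so that both the per-practice margins and the global stage ×
stratum table are met exactly.  The within-practice demographic
composition is not part of the published record and is arbitrary (but
deterministic).

## The practice simulator

The simulator is the test bed: it produces logs with a known ground
truth so the funnel, the bias tests, the registry audit and the
suppression policy can be validated statistically.

* **Panel.**  `panel_size` eligible patients i.i.d. from a probability
  vector over the five strata; the default is the reference study's
  net-sample demography (72% women; within-sex age mixes as published).
  Birth dates are uniform within each band at study start (open-ended
  bands capped at 95 years).  A small fraction (default 0.15%) is
  deceased — their charts may still be opened.
* **Visits.**  Per-patient EPR-open counts are homogeneous Poisson with
  mean `visit_rate × study_months`, times uniform in the window.  No
  published per-practice visit frequency exists; the default of 0.6
  opens per patient-month (~7 per year) reflects the consulting
  frequency of a 60+ general-practice population.  Each open is flagged
  physically-present with probability `1 − not_present_prob`
  (default 0.25): charts are routinely opened for administrative reasons
  without the patient in the practice.  Opens inside a downtime window
  are marked unrecorded — invisible to the registry, visible to the
  oracle sidecar.
* **Staff.**  At each recorded open of an alertable record the staff
  responds with probability `p_respond` times an optional per-stratum
  multiplier (the bias injector, capped at 1), else clicks the reminder
  off.  A response reviews eligibility: deceased patients are noted as
  such; absent patients can only be excluded; present patients are
  excluded with `p_exclude_given_respond` or contacted, and contacts
  refuse with `p_refuse_given_contact` or consent and start the survey,
  which is interrupted with `p_interrupt_given_start` (resuming and
  completing at the patient's next recorded visit) or completed on the
  spot.

Default staff parameters are calibrated to the reference study's funnel
proportions under the default visit rate: with per-open response
probability p and Poisson(λ = 7.2) opens per patient-year, the reviewed
share is 1 − e^{−λp}; p = 0.054 gives the observed 32%.  Exclusions are
63% of reviews overall; since reviews of absent patients always exclude,
the conditional probability for present patients solves
0.25 + 0.75·x = 0.63, giving x = 0.51.  Refusal is 20% of contacts as
observed.  With these defaults a 16,067-patient run reproduces the
reference funnel proportions to within sampling noise (reviewed ≈ 32%,
contacted ≈ 12%, enrolled ≈ 9.5%).

Randomness: one `numpy` Generator per practice, keyed by
`(run seed, crc32(practice_id))` through `SeedSequence`, so practices are
independent but the whole run is bit-reproducible from one seed.

**What the simulator does not emulate** — seasonal or appointment-driven
visit patterns, staff fatigue or learning, correlation between a
patient's demography and visit frequency, and all non-demographic
selection (education, communicativeness, "slow-hours" visiting).  Passing
tests therefore show that the *accounting and inference machinery* is
correct under a plausible generative model, not that real practices
behave like the model; in particular the published 91% real-world
registry overlap reflects causes (update patches, partial outages) that
the simulator does not model, and is not a reproduction target.

## Bias testing and adaptive suppression

The χ² test compares enrolees against the net-sample **non**-enrolees by
default (`enrolled_vs_rest`), keeping the two groups disjoint as the
independence test assumes; the overlapping enrolled-vs-net framing is
available as an explicit mode for reproducing analyses phrased that way
(its p-values are conservative).  No continuity correction is applied;
df = k − 1 for k strata.  The implementation is scipy's contingency
machinery and is checked in the tests against an independently
hand-coded Pearson formula to 1e-9.

Representation ratios use unrounded shares and are scale-invariant.

The suppression policy mutes a stratum while its enrolled share exceeds
its net share by more than `tolerance` percentage points (default 5) and
releases it as soon as the excess falls back within tolerance; nothing is
suppressed before `min_enrolled` enrolments (default 50) so early noise
cannot mute anyone.  The mechanism was proposed without parameters; the
defaults are the package's choice: 5 points is well above the sampling
noise of a stratum share at n = 50 (SE ≤ 7 points, falling below 5 by
n ≈ 100), so false suppressions are rare while genuine bias of the size
observed in the reference study (≈ 9 points excess for women 60–69)
triggers quickly.  During simulation the policy is re-evaluated after
every enrolment against the accruing identified-vs-enrolled demography.

## Registry-consistency audit

Overlap is |registry ∩ oracle| / |oracle| with the full-panel database
query as denominator, matching a validation of the live registry against
complete practice-software queries.  Under the simulator's assumptions a
patient with Poisson(λ) visits uniform in time and a downtime window of
fraction f is invisible to the registry iff all visits fall in the
window, so the expected overlap is
1 − (e^{−λ(1−f)} − e^{−λ}) / (1 − e^{−λ}); the tests and the acceptance
script compare measured overlap against this closed form (3 SE at the
pooled oracle size over 50 seeds).

## Problem sizes and numerical choices

The statistical checks use: a 16,067-patient panel for demography and
funnel calibration; ~10,000 simulated contacts for refusal-probability
recovery (3 binomial SE); 50 seeds × 300-patient practices for the
downtime audit; and a 50-seed paired comparison at 1,500 patients
(≈ 500–600 enrolees per arm) for the suppression effect, comparing
medians of the total-variation distance between enrolled and net
demography.  These sizes keep every check's power high (the suppression
effect, ≈ 0.01 absolute TV, exceeds the median's sampling noise several
times over) while the full suite and the acceptance script each run in
about a minute.

Degenerate inputs are explicit errors, not warnings: zero expected cells
in a contingency table, a zero net share in a representation ratio, an
empty oracle set, demography vectors off unit sum by more than 1e-9, and
any protocol-illegal event log.

## Known limitations

* The fixture log's within-practice demography and all its timestamps
  are synthetic; only the published margins are real.
* The staff model is memoryless per open; real staff behaviour shows
  fatigue and practice-level heterogeneity that the single-probability
  model flattens (the per-stratum multipliers are a deliberate bias
  injector, not a behavioural theory).
* Suppression is evaluated against identified-so-far demography, which
  early in a study is itself noisy; `min_enrolled` guards the enrolled
  side only.
* The χ² tests treat patients as independent; clustering by practice is
  ignored, as in the source analysis.
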