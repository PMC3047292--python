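# ctalert

A clinical trial alert (CTA) recruitment engine for general-practice
research, with a synthetic practice simulator and selection-bias monitor.

Recruiting patients through their own GP produces real-world samples, but
busy practices under-recruit, and — worse — nobody can usually say *who*
was left out, because the population at risk is never recorded.  A CTA
tool closes that gap: it watches the practice software's electronic
patient records (EPRs), and whenever the chart of a demographically
eligible patient is opened it (a) fires an on-screen reminder prompting
the staff to review, contact and survey the patient, and (b) transmits a
pseudonymised record (study id, sex, age band) to the study centre.  The
registry therefore contains the *whole* net sample, not just the
enrolees, so recruitment efficiency and demographic selection bias become
measurable quantities instead of guesses.

`ctalert` implements that engine end to end:

* **Eligibility & identification** — the net-sample rule (women ≥ 60,
  men ≥ 70, completed years at each EPR opening) and keyed-HMAC
  pseudonymisation re-identifiable only with the practice-local key map.
* **Recruitment state machine** — events (`epr_open`, `click_off`,
  `exclude`, `contact`, `refuse`, `consent`, `survey_start/interrupt/
  complete`, `deceased_noted`) folded into per-patient states; `EXCLUDED`,
  `REFUSED`, `ENROLLED` and `DECEASED` are absorbing, ignored reminders
  and unfinished surveys stay "open" and keep alerting.
* **Funnel accounting** — the stage partition
  `identified = open + excluded + contacted`,
  `contacted = refused + enrolled`, per-practice enrolment rates and
  target achievement, and small/large practice stratification.
* **Bias monitor** — stage × stratum demography over the five strata
  (F 60–69, F 70–79, F 80+, M 70–79, M 80+), Pearson χ² tests of
  enrolled-vs-net demography, representation ratios (enrolled share ÷ net
  share), a registry-completeness audit, and an adaptive policy that
  suppresses the reminder for overrepresented strata until enrolment
  re-approaches the net sample.
* **Practice simulator** — panels drawn from a configurable demography,
  Poisson visit streams, software downtime windows, and probabilistic
  staff behaviour (with per-stratum bias injectors), producing JSON-Lines
  event logs that replay legally through the state machine.

A reference dataset — the full printed accounting of a 25-practice,
12-month osteoporosis-survey recruitment study — is packaged and can be
expanded into a protocol-legal event log for end-to-end testing.

## Worked example

```python
import ctalert as ct
from ctalert.datasets import reference_event_log

registry = ct.replay(reference_event_log())
counts = ct.funnel_counts(registry)
print(ct.consort_text(counts))
```

```
identified (net sample)         16,067
|- open / no response           10,906   (incl. 43 surveys in progress)
|- excluded                      3,248   (incl. 22 deceased)
`- contacted                     1,913
   |- refused                      387
   `- enrolled                   1,526
reviewed (excluded+contacted)    5,161
```

The staff acted on 5,161 of 16,067 alerts (32%), contacted 1,913 patients
(12%), and enrolled 1,526 — 9.5% of the net sample and 30.5% of the
5,000-patient recruitment goal (200 per practice; only one practice
reached it).  The bias monitor quantifies who was enrolled:

```python
table = ct.stage_demography(registry)
print(ct.sex_representation_ratio("M", table))        # 0.670
print(ct.chi_square_bias_test(
    table.sex_counts("net_sample").to_numpy(),
    table.sex_counts("enrolled").to_numpy()))
```

```
0.6702084121535786
chi2 = 71.191, df = 1, p = 3.312e-17
```

Men are 28.0% of the net sample but only 18.7% of enrolees (ratio 0.670);
older patients of both sexes are likewise underrepresented.  With an
event log on disk the same surface is available from a shell:

```
ctalert simulate --config run.yaml --out log.jsonl --oracle oracle.jsonl
ctalert replay log.jsonl
ctalert funnel log.jsonl --csv practices.csv
ctalert bias log.jsonl --csv strata.csv
ctalert report log.jsonl --outdir reports/
```

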