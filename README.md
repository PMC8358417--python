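# esmo-mcbs — clinical-benefit grading for recurrent ovarian cancer trials

Most systemic therapies for recurrent epithelial ovarian cancer are
palliative, and their trials report a familiar bundle of summary
statistics: median progression-free and overall survival in each arm, a
hazard ratio with its 95% confidence interval, response rates, and (less
reliably) quality-of-life and toxicity outcomes. The **ESMO Magnitude of
Clinical Benefit Scale (ESMO-MCBS)** turns that bundle into a single grade
from 1 to 5, where 4–5 means *substantial* clinical benefit. This package
implements the palliative arm of that scale as a tested rule engine,
together with the systematic-review screening gate that decides which
randomised trials may be graded at all — so oncologists, guideline
developers and HTA analysts can grade curated trial records reproducibly
instead of by hand, and audit every rule that fired.

## What the engine computes

For a trial record that passes screening (randomised, adequate comparator
for its setting, statistically significant benefit of the study arm under
the trial's prespecified, multiplicity-controlled test):

1. **Evaluation form** from the primary endpoint: form **2a** for OS (or
   PFS-primary with a *confirmed* secondary OS benefit), **2b** for
   PFS-only benefit, **2c** for non-inferiority / QoL–toxicity
   comparisons, **3** for response rate.
2. **Preliminary grade** from threshold tables on the **lower bound L of
   the 95% CI of the hazard ratio** and the absolute median gain *G*
   (months), stratified by the control-arm median. E.g. form 2a with
   control OS > 12 months awards 4 when L ≤ 0.70 and G ≥ 5; form 2b with
   control PFS ≤ 6 months awards its maximum 3 when L ≤ 0.65 and
   G ≥ 1.5. All bounds are inclusive, rows act as floors evaluated
   top-down, and the grade is monotone in (−L, +G).
3. **Adjustment (±1)**: upgraded for demonstrated QoL benefit (global or
   prespecified subscale) or reduced grade 3–4 toxicity; for a PFS-only
   benefit, downgraded when a *published* OS result is null and QoL shows
   no improvement. While OS/QoL remain unpublished the downgrade is
   suspended — absent is not zero.
4. **Final grade** = clamp(preliminary + adjustment, 1, 5), with a full
   rationale trace.

Trials failing the gate come back `NOT_GRADED` with explicit reasons — a
first-class outcome, not an error.

The package also ships a curated corpus transcribing the published
summary tables of a systematic review of recurrent-ovarian-cancer trials
(19 graded trials expanded to 24 grade-bearing rows, plus 27 trials
without a significant benefit), a relative-benefit comparator network
(graded trials as edges comparator → experimental arm), and a seeded
synthetic-trial generator for property testing.

## Worked example

```python
from esmo_mcbs import *

record = TrialRecord(
    trial_id="example", setting=Setting.PLATINUM_RESISTANT,
    design=Design.PHASE3_RCT, n=361,
    experimental_label="bevacizumab plus chemotherapy",
    comparator_label="chemotherapy",
    primary_endpoint=PrimaryEndpoint.PFS,
    endpoints=[
        EndpointSummary(endpoint=Endpoint.PFS, control_median=3.4, gain=3.3,
                        hazard_ratio=0.48,
                        hr_ci=ConfidenceInterval(lower=0.38, upper=0.60),
                        significant=Significance.CONFIRMED),
        EndpointSummary(endpoint=Endpoint.OS, control_median=13.3, gain=3.3,
                        hazard_ratio=0.85,
                        hr_ci=ConfidenceInterval(lower=0.66, upper=1.08),
                        significant=Significance.NOT_SIGNIFICANT),
    ],
    evidence=EvidenceFlags(qol_reported=True, qol_subscale_improved=True),
    comparator_class=ComparatorClass.GUIDELINE_LISTED,
)
print(grade_trial(record))
```

prints (abridged):

```
form 2b: preliminary 3, adjustment +1, final grade 4
  - form 2b (control PFS 3.4 months, stratum <= 6): HR CI lower 0.38,
    gain 3.3 months -> preliminary 3
  - +1: QoL benefit (global or prespecified subscale) or reduced toxicity
  - final grade = clamp(3 +1) = 4
```

Reading: the PFS effect clears the short-control-median form-2b bands
(preliminary 3, the form's maximum), and the prespecified
patient-reported-outcome subscale improvement upgrades it to 4 —
substantial benefit. Re-grading the whole packaged corpus
(`examples/reproduce_published_grades.py`) reports **0 mismatches**
against the printed scores and exactly **three** treatments at grade ≥ 4:
paclitaxel plus platinum (platinum-sensitive), bevacizumab added to
chemotherapy (platinum-resistant), and adavosertib plus gemcitabine.

More narrative scripts live in `examples/`; a thin CLI (`mcbs screen`,
`mcbs grade`, `mcbs network`, `mcbs simulate`, `mcbs corpus`) wraps the
same functions for shell use.

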