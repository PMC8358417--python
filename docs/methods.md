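# Methods

## Scope and model

The package grades *palliative* systemic therapies for recurrent
epithelial ovarian cancer on the ESMO-MCBS 1–5 scale from published
summary statistics only. Chemotherapy after relapse — even following
secondary debulking — is treated as palliative throughout, so only the
palliative evaluation forms (2a, 2b, 2c, 3) are implemented; the
curative-intent form is out of scope, as is any re-analysis of
patient-level survival or QoL instrument data: medians, gains, hazard
ratios and CIs are taken as printed.

A *record* is one trial or one prespecified subgroup row of a trial
(ITT / gBRCA / HRD …), mirroring how trial reports print one grade per
row. A parent record plus per-subgroup records keeps the ≤3-subgroup
multiplicity rule checkable at the corpus level.

## Screening gate

A record may be graded iff all of the following hold:

* randomised design (category I: phase III, adequate comparator, OS/PFS
  primary; category II: other potentially scorable randomised studies;
  category III — non-randomised designs — is never graded);
* not terminated early and not superseded by a higher-quality trial of
  the same treatment (curated flags — the engine does not infer them);
* adequate comparator for the setting: platinum-based chemotherapy in
  platinum-sensitive disease (non-platinum controls are inferior there),
  any guideline-listed option in platinum-resistant disease, placebo/no
  further treatment for maintenance after response to platinum. The
  comparator *class* is a curated annotation; the engine only applies the
  setting rule to it. "Large" is deliberately not operationalised by a
  sample-size cutoff: no eligible randomised trial in the corpus was
  excluded for size, so a cutoff would be an invention;
* not a non-prespecified (exploratory) subgroup analysis, and at most
  three prespecified subgroup rows per trial;
* a statistically significant benefit of the study arm on the primary
  endpoint — or a confirmed secondary OS benefit — where *confirmed*
  means the trial's prespecified, multiplicity-controlled test was met.
  An exploratory analysis is never confirmed, however small its p-value
  (e.g. an uncorrected OS analysis, or a post-hoc mutation-confirmed
  subset).

Exclusions carry explicit reasons; `NOT_GRADED` is a first-class outcome.
The gate is monotone: turning a null result into a confirmed one can only
admit a record.

## Threshold tables and their semantics

Forms 2a/2b are tables over **L**, the lower 95% confidence bound of the
hazard ratio, and **G**, the absolute median gain in months, stratified
by the control-arm median (2a: 12 months; 2b: 6 months; a control median
exactly at the bound uses the low stratum). The criterion is the *CI
bound*, not the HR point estimate — the only reading consistent with the
graded corpus (a trial with HR 0.82 but L 0.69 earns form-2a grade 4; one
with HR 0.81 but L 0.68 earns form-2b grade 1).

All comparisons are inclusive (the trabectedin row, with L exactly 0.65
and G exactly 1.5, must reach preliminary 3). Rows are evaluated top-down
and act as **floors**: a row fires when L is at most its cap and G at
least its floor, and the first (highest) firing row gives the grade, so
the upper edge of each band is implied by the rows above it. The
alternative — window bands with explicit gain ceilings (the
`max_gain_exclusive` field exists for them) — would make the grade
non-monotone: a trial with L = 0.70 and a *5-month* gain would score
lower than the same trial with a 2-month gain. The package adopts the
floor semantics as a design decision: it reproduces every fixture in the
graded corpus (no published row sits in a discriminating cell) and keeps
the preliminary grade monotone in (−L, +G), which the property suite
enforces over a 2112-cell grid. Form 2b is capped at 3 by construction.

Form 2a's alternative pathway via 2–3-year survival-percentage gains is
accepted as an input field but exercised by no fixture; it applies only
when medians are not evaluable. Form 2c's full ladder (4 = global QoL or
grade 3–4 toxicity improvement on top of non-inferior efficacy, 3 =
prespecified subscale improvement or reduced early discontinuation, 2 =
non-inferior efficacy alone, 1 otherwise) and form 3's upper band
(ORR ≥ 60 → 3) are each constrained by a single published example; the
remaining bands are documented package conventions. A non-inferiority
trial with no QoL/toxicity advantage whatsoever is curated as not
significant (it demonstrates no *benefit*), so the "non-inferior only →
2" band is reachable through the API but not exercised by the corpus.

## Adjustment semantics

* Form 2b (PFS-only benefit): **+1** for a demonstrated QoL benefit —
  global, or a *prespecified* subscale — or reduced grade 3–4 toxicity;
  **−1** when a published OS result is null *and* QoL was reported
  without improvement, or when toxicity increased without a QoL benefit;
  offsetting evidence (QoL benefit and increased toxicity) resolves to 0
  and is logged in the rationale.
* The downgrade is **suspended while OS/QoL are unpublished or
  exploratory** — this is why "absent" must never be conflated with
  zero anywhere in the data model.
* Form 2a: +1 only (toward grade 5); an OS-graded therapy is never
  downgraded.
* Forms 2c and 3: no adjustment.

Final = clamp(preliminary + adjustment, 1, 5); |final − preliminary| ≤ 1
always.

## Curated corpus

`esmo_mcbs/data/corpus_trials.csv` transcribes the three published
summary tables: 14 phase-III and 5 randomised phase-II trials with
significant results (24 grade-bearing rows once subgroup rows are
expanded, plus the niraparib ITT row, which prints no data, and its
exploratory HRD+ subset row, which prints data but no score) and 27
trials without a significant benefit. `corpus_expected.csv` pins the
printed form, preliminary grade, adjustment and final grade per row;
`run_corpus_check()` re-grades everything and reports mismatches. Files
are sha256-checksummed at load.

Curation notes: hazard ratios printed without CIs are stored as bare
point estimates (CI containment is validated only when both are present);
one trebananib OS gain is printed in a typographically ambiguous digit
run and is recorded as 1.0 month; a time-to-progression primary endpoint
is folded into PFS; maintenance patient totals match the printed setting
total exactly (3394), while the printed sensitive/resistant totals differ
from the sums of the printed per-trial sample sizes (5876 and 7533 by
column sum) — the corpus keeps the per-trial numbers. The literature-
search figures (1127 papers screened, 61 reports, 98% inter-observer
agreement) describe a human process and are carried as metadata only.

## Synthetic generator

`generate_trials` emulates the corpus population: setting drawn
uniformly; control median log-uniform within per-setting ranges spanning
the printed control medians (sensitive 5–31, maintenance 4–39, resistant
2–19 months); true hazard ratio uniform on 0.2–1.25; observed log-HR
drawn around the true value with SE(log HR) = 2/√events (events uniform
on 50–500 by default), the standard large-sample approximation for a 1:1
randomised comparison; 95% CI from the same SE; gain = control·(1/HR − 1)
with multiplicative log-normal noise (σ = 0.2); significance = CI
excludes 1 in the benefit direction; evidence flags Bernoulli with rates
loosely matching how often the corpus reports QoL (0.6) and finds
improvements (rare). Endpoint mix defaults to 20% OS / 70% PFS / 10% ORR,
reflecting the predominance of PFS primaries.

What this does **not** emulate: correlated PFS/OS effects within a trial,
crossover dilution of OS, informative censoring, publication bias, or
any relationship between evidence flags and effect sizes. Passing
property tests on synthetic data therefore demonstrates rule-engine
correctness (bounds, monotonicity, oracle equivalence, power direction),
not calibration against real trial populations — the curated corpus is
the ground truth for that.

`generate_grade_grid` is deterministic: L ∈ {0.30…0.80 step 0.05} ×
G ∈ {0.5…6.0 step 0.5} × control ∈ {3, 5.9, 6, 6.1, 11.9, 12, 12.1, 24} ×
{OS, PFS}, i.e. 2112 cells straddling every stratum bound and band edge.

## Numerical and degenerate-input choices

Months are decimal numbers as printed; no date arithmetic. Absent fields
are `None`/`""`, distinct from zero. Validation is total — it returns
violations (naming field and rule) and never raises, so one malformed row
cannot abort a batch. Threshold comparisons are plain float comparisons:
the inputs are table values with at most two decimals, so no epsilon is
needed. Ties: control median exactly at a stratum bound → low stratum;
L or G exactly at a band edge → inside the band; offsetting ±1 evidence
→ 0. Grid CI/gain values are built from exact decimal steps rounded to
two places to avoid accumulation error.

## Problem sizes

The shipped suites grade the 53-row corpus, the 2112-cell grid, and
10 000 synthetic records for the oracle-equivalence check; these sizes
give full boundary coverage of the threshold tables while keeping the
whole test run in seconds.

## Known limitations

* The scale itself is coarse: a single month of gain can move a grade,
  and the package inherits that discreteness by design.
* Comparator networks attach grades to edges only; no indirect
  comparisons are estimated, because grades earned against different
  comparators are not exchangeable.
* QoL/toxicity evidence enters as curated booleans; the package does not
  judge instrument quality or effect sizes of patient-reported outcomes.
* Screening flags (superseded, terminated early, comparator class) encode
  reviewer judgement; the engine applies but cannot audit them.
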