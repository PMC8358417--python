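"""ESMO-MCBS grading of palliative therapies: form choice, preliminary
grade, QoL/toxicity adjustment, final grade 1-5.

The scale's palliative evaluation forms are threshold tables on the
*lower bound of the 95% CI of the hazard ratio* (L) and the *absolute
median gain* in months (G), stratified by the control-arm median:

form 2a (overall survival; stratum bound 12 months)
    control <= 12:  4 if L <= 0.65 and G >= 3;   3 if L <= 0.65 and G >= 2.5;
                    2 if L <= 0.70 and G >= 1.5; else 1
    control  > 12:  4 if L <= 0.70 and G >= 5;   3 if L <= 0.70 and G >= 3;
                    2 if L <= 0.75 and G >= 1.5; else 1

form 2b (progression-free survival; stratum bound 6 months; capped at 3)
    control <= 6:   3 if L <= 0.65 and G >= 1.5; 2 if L <= 0.65; else 1
    control  > 6:   3 if L <= 0.65 and G >= 3;   2 if L <= 0.65; else 1

Rows are evaluated top-down and act as *floors*: the first (highest) row
whose HR bound and gain floor are both met yields the grade, so the
preliminary grade is monotone — a lower CI bound or a larger gain can
never demote a trial.  All comparisons are inclusive (a CI lower bound of
exactly 0.65 with a gain of exactly 1.5 months earns form-2b grade 3).

Form 2c grades non-inferiority/QoL-primary comparisons on QoL and toxicity
evidence alone; form 3 grades single-endpoint response-rate comparisons on
the ORR percentage.

The preliminary grade is then adjusted by at most +-1: upgraded for a
demonstrated QoL benefit (global, or a prespecified subscale) or reduced
grade 3-4 toxicity; for a PFS-only benefit, downgraded when a published OS
result is null and QoL shows no improvement (or toxicity is increased
without a QoL benefit).  While OS and QoL remain unpublished the downgrade
is *not* applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .records import (
    Endpoint,
    EndpointSummary,
    Form,
    GradedResult,
    PrimaryEndpoint,
    Significance,
    TrialRecord,
)
from .screening import ScreeningDecision, gradeability_gate


class MissingFieldError(ValueError):
    """A form needs a summary statistic the record does not carry."""


class NotGradableError(ValueError):
    """No evaluation form applies; carries the reason."""


@dataclass(frozen=True)
class ThresholdRow:
    """One grade band: HR CI-lower cap and gain floor (inclusive).

    ``max_gain_exclusive`` can carve an explicit upper gain edge out of a
    band; the shipped tables leave it unset — upper edges are implied by
    the higher rows under top-down evaluation, which keeps the grade
    monotone in benefit.
    """

    grade: int
    max_hr_ci_lower: float
    min_gain: float
    max_gain_exclusive: Optional[float] = None

    def matches(self, ci_lower: float, gain: float) -> bool:
        if ci_lower > self.max_hr_ci_lower or gain < self.min_gain:
            return False
        if self.max_gain_exclusive is not None and gain >= self.max_gain_exclusive:
            return False
        return True


@dataclass(frozen=True)
class FormThresholds:
    """Threshold table of one evaluation form, split by control-median stratum."""

    form: Form
    stratum_bound: float  # months of control-arm median; <= bound -> low stratum
    low_stratum: tuple[ThresholdRow, ...]
    high_stratum: tuple[ThresholdRow, ...]

    def rows_for(self, control_median: float) -> tuple[ThresholdRow, ...]:
        # a control median exactly at the bound uses the low ("<=") stratum
        return self.low_stratum if control_median <= self.stratum_bound else self.high_stratum

    def preliminary(self, control_median: float, gain: float, ci_lower: float) -> int:
        for row in self.rows_for(control_median):
            if row.matches(ci_lower, gain):
                return row.grade
        return 1


FORM_2A = FormThresholds(
    form=Form.F2A,
    stratum_bound=12.0,
    low_stratum=(
        ThresholdRow(4, 0.65, 3.0),
        ThresholdRow(3, 0.65, 2.5),
        ThresholdRow(2, 0.70, 1.5),
    ),
    high_stratum=(
        ThresholdRow(4, 0.70, 5.0),
        ThresholdRow(3, 0.70, 3.0),
        ThresholdRow(2, 0.75, 1.5),
    ),
)

FORM_2B = FormThresholds(
    form=Form.F2B,
    stratum_bound=6.0,
    low_stratum=(
        ThresholdRow(3, 0.65, 1.5),
        ThresholdRow(2, 0.65, float("-inf")),
    ),
    high_stratum=(
        ThresholdRow(3, 0.65, 3.0),
        ThresholdRow(2, 0.65, float("-inf")),
    ),
)


def _require(summary: EndpointSummary, form: Form) -> tuple[float, float, float]:
    for name in ("control_median", "gain"):
        if getattr(summary, name) is None:
            raise MissingFieldError(
                f"form {form.value} needs {summary.endpoint.value}.{name}"
            )
    if summary.hr_ci is None:
        raise MissingFieldError(f"form {form.value} needs {summary.endpoint.value}.hr_ci")
    return summary.control_median, summary.gain, summary.hr_ci.lower


def grade_form_2a(os_summary: EndpointSummary) -> int:
    """Preliminary grade (1-4) for an overall-survival benefit."""
    control, gain, lower = _require(os_summary, Form.F2A)
    return FORM_2A.preliminary(control, gain, lower)


def grade_form_2b(pfs_summary: EndpointSummary) -> int:
    """Preliminary grade (1-3) for a PFS-only benefit; never exceeds 3."""
    control, gain, lower = _require(pfs_summary, Form.F2B)
    return FORM_2B.preliminary(control, gain, lower)


def grade_form_2c(record: TrialRecord) -> int:
    """Preliminary grade (1-4) for non-inferiority / QoL-toxicity comparisons.

    With non-inferior efficacy established: 4 for an improved global QoL or
    reduced grade 3-4 toxicity, 3 for a prespecified subscale improvement
    or reduced early discontinuation, 2 for non-inferior efficacy alone;
    1 otherwise.
    """
    e = record.evidence
    noninferior = _noninferior_efficacy(record)
    if not noninferior and not (
        e.any_qol_or_toxicity_benefit or e.early_discontinuation_reduced
    ):
        raise NotGradableError(
            "form 2c requires QoL/toxicity evidence or demonstrated non-inferior efficacy"
        )
    if noninferior and (e.qol_global_improved or e.toxicity_reduced):
        return 4
    if noninferior and (e.qol_subscale_improved or e.early_discontinuation_reduced):
        return 3
    if noninferior:
        return 2
    return 1


def _noninferior_efficacy(record: TrialRecord) -> bool:
    if record.primary_endpoint is PrimaryEndpoint.NONINFERIORITY:
        pfs = record.endpoint(Endpoint.PFS)
        return pfs is not None and pfs.significant is Significance.CONFIRMED
    if record.primary_endpoint is PrimaryEndpoint.QOL_TOX:
        qol = record.endpoint(Endpoint.QOL_TOX)
        return qol is not None and qol.significant is Significance.CONFIRMED
    return False


def grade_form_3(orr_summary: EndpointSummary) -> int:
    """Preliminary grade (1-3) for a response-rate comparison."""
    if orr_summary.orr_pct is None:
        raise MissingFieldError("form 3 needs orr.orr_pct")
    pct = orr_summary.orr_pct
    if pct >= 60:
        return 3
    if pct >= 20:
        return 2
    return 1


def select_form(record: TrialRecord) -> Form:
    """Choose the evaluation form from the primary endpoint.

    Form 2a applies when OS is the primary endpoint, or when a PFS-primary
    trial carries a *confirmed* (prespecified, multiplicity-controlled)
    secondary OS benefit; PFS-primary trials without one fall to form 2b.
    Non-inferiority and QoL/toxicity primaries use form 2c; response-rate
    primaries use form 3.
    """
    pe = record.primary_endpoint
    if pe is PrimaryEndpoint.OS:
        return Form.F2A
    if pe is PrimaryEndpoint.PFS:
        os_summary = record.endpoint(Endpoint.OS)
        if os_summary is not None and os_summary.significant is Significance.CONFIRMED:
            return Form.F2A
        return Form.F2B
    if pe in (PrimaryEndpoint.NONINFERIORITY, PrimaryEndpoint.QOL_TOX):
        return Form.F2C
    if pe is PrimaryEndpoint.ORR:
        return Form.F3
    raise NotGradableError(f"no evaluation form for primary endpoint {pe.value!r}")


def _adjustment_with_reason(
    form: Form, preliminary: int, record: TrialRecord
) -> tuple[int, str]:
    e = record.evidence
    if form in (Form.F2C, Form.F3):
        return 0, f"form {form.value}: no QoL/toxicity adjustment applies"
    upgrade = e.any_qol_or_toxicity_benefit
    if form is Form.F2A:
        if upgrade:
            return +1, "+1: QoL/toxicity improvement on top of an OS benefit"
        return 0, "no adjustment: no QoL/toxicity improvement demonstrated"

    # form 2b: PFS-only benefit
    os_summary = record.endpoint(Endpoint.OS)
    os_reported_null = (
        os_summary is not None
        and os_summary.significant is Significance.NOT_SIGNIFICANT
    )
    downgrade = (os_reported_null and e.qol_reported and not upgrade) or (
        e.toxicity_increased and not upgrade
    )
    if upgrade and e.toxicity_increased:
        return 0, "no adjustment: QoL benefit and increased toxicity offset (tie)"
    if upgrade:
        return +1, "+1: QoL benefit (global or prespecified subscale) or reduced toxicity"
    if downgrade:
        return -1, "-1: no OS benefit and no QoL improvement demonstrated"
    return 0, (
        "no adjustment: OS/QoL not published or exploratory — downgrade not applied"
        if not os_reported_null
        else "no adjustment"
    )


def compute_adjustment(form: Form, preliminary: int, record: TrialRecord) -> int:
    """The +-1 QoL/toxicity adjustment of the preliminary grade."""
    return _adjustment_with_reason(form, preliminary, record)[0]


def _clamp(x: int, lo: int = 1, hi: int = 5) -> int:
    return max(lo, min(hi, x))


def grade_trial(
    record: TrialRecord, decision: Optional[ScreeningDecision] = None
) -> GradedResult:
    """Full grading of one record: gate -> form -> preliminary -> adjustment.

    Records failing the gate come back as NOT_GRADED with the screening
    reasons in the rationale; a grade is always accompanied by the ordered
    list of rules that produced it.
    """
    if decision is None:
        decision = gradeability_gate(record)
    if not decision.included:
        return GradedResult(
            trial_id=record.trial_id,
            form=Form.NOT_GRADED,
            preliminary=None,
            adjustment=0,
            final=None,
            rationale=["not graded: " + r for r in decision.reasons],
        )

    rationale = [f"screening: included (category {decision.category.value})"]
    try:
        form = select_form(record)
    except NotGradableError as exc:
        return GradedResult(
            trial_id=record.trial_id,
            form=Form.NOT_GRADED,
            preliminary=None,
            adjustment=0,
            final=None,
            rationale=rationale + [f"not graded: {exc}"],
        )

    if form is Form.F2A:
        summary = record.endpoint(Endpoint.OS)
        if summary is None:
            raise MissingFieldError("form 2a selected but no OS summary present")
        preliminary = grade_form_2a(summary)
        origin = (
            "primary endpoint OS"
            if record.primary_endpoint is PrimaryEndpoint.OS
            else "primary endpoint PFS with confirmed OS benefit"
        )
        rationale.append(f"form 2a selected: {origin}")
        stratum = "<= 12" if summary.control_median <= 12 else "> 12"
        rationale.append(
            f"form 2a (control OS {summary.control_median} months, stratum {stratum}): "
            f"HR CI lower {summary.hr_ci.lower}, gain {summary.gain} months "
            f"-> preliminary {preliminary}"
        )
    elif form is Form.F2B:
        summary = record.endpoint(Endpoint.PFS)
        if summary is None:
            raise MissingFieldError("form 2b selected but no PFS summary present")
        preliminary = grade_form_2b(summary)
        rationale.append("form 2b selected: primary endpoint PFS without confirmed OS benefit")
        stratum = "<= 6" if summary.control_median <= 6 else "> 6"
        rationale.append(
            f"form 2b (control PFS {summary.control_median} months, stratum {stratum}): "
            f"HR CI lower {summary.hr_ci.lower}, gain {summary.gain} months "
            f"-> preliminary {preliminary}"
        )
    elif form is Form.F2C:
        try:
            preliminary = grade_form_2c(record)
        except NotGradableError as exc:
            return GradedResult(
                trial_id=record.trial_id,
                form=Form.NOT_GRADED,
                preliminary=None,
                adjustment=0,
                final=None,
                rationale=rationale + [f"not graded: {exc}"],
            )
        rationale.append("form 2c selected: non-inferiority / QoL-toxicity comparison")
        rationale.append(f"form 2c evidence ladder -> preliminary {preliminary}")
    else:  # Form.F3
        summary = record.endpoint(Endpoint.ORR)
        if summary is None:
            raise MissingFieldError("form 3 selected but no ORR summary present")
        preliminary = grade_form_3(summary)
        rationale.append("form 3 selected: primary endpoint ORR")
        rationale.append(f"form 3 (ORR {summary.orr_pct}%) -> preliminary {preliminary}")

    adjustment, why = _adjustment_with_reason(form, preliminary, record)
    rationale.append(why)
    final = _clamp(preliminary + adjustment)
    rationale.append(f"final grade = clamp({preliminary} {adjustment:+d}) = {final}")
    return GradedResult(
        trial_id=record.trial_id,
        form=form,
        preliminary=preliminary,
        adjustment=adjustment,
        final=final,
        rationale=rationale,
    )


def grade_all(records: Sequence[TrialRecord]) -> list[GradedResult]:
    """Screen and grade a corpus; one result per record, order preserved."""
    from .screening import screen_all

    decisions = screen_all(records)
    return [grade_trial(r, decisions[r.trial_id]) for r in records]
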