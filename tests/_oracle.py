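"""Independent brute-force re-implementation of the grading rules.

Deliberately written as flat, exhaustive condition lists with no shared
code, tables or helpers from the package, so it can serve as an oracle
for the data-driven threshold engine.
"""

from __future__ import annotations

from esmo_mcbs import Endpoint, Form, Significance, TrialRecord


def oracle_os_preliminary(control: float, gain: float, ci_lower: float) -> int:
    if control <= 12:
        if ci_lower <= 0.65 and gain >= 3:
            return 4
        if ci_lower <= 0.65 and gain >= 2.5:
            return 3
        if ci_lower <= 0.70 and gain >= 1.5:
            return 2
        return 1
    else:
        if ci_lower <= 0.70 and gain >= 5:
            return 4
        if ci_lower <= 0.70 and gain >= 3:
            return 3
        if ci_lower <= 0.75 and gain >= 1.5:
            return 2
        return 1


def oracle_pfs_preliminary(control: float, gain: float, ci_lower: float) -> int:
    if control <= 6:
        if ci_lower <= 0.65 and gain >= 1.5:
            return 3
        if ci_lower <= 0.65:
            return 2
        return 1
    else:
        if ci_lower <= 0.65 and gain >= 3:
            return 3
        if ci_lower <= 0.65:
            return 2
        return 1


def oracle_form(record: TrialRecord) -> Form:
    pe = record.primary_endpoint.value
    if pe == "os":
        return Form.F2A
    if pe == "pfs":
        os_summary = record.endpoint(Endpoint.OS)
        if os_summary is not None and os_summary.significant is Significance.CONFIRMED:
            return Form.F2A
        return Form.F2B
    if pe in ("noninferiority", "qol_tox"):
        return Form.F2C
    return Form.F3


def oracle_adjustment(record: TrialRecord, form: Form) -> int:
    e = record.evidence
    improved = e.qol_global_improved or e.qol_subscale_improved or e.toxicity_reduced
    if form is Form.F2A:
        return 1 if improved else 0
    if form is not Form.F2B:
        return 0
    if improved and e.toxicity_increased:
        return 0
    if improved:
        return 1
    os_summary = record.endpoint(Endpoint.OS)
    os_null = os_summary is not None and os_summary.significant is Significance.NOT_SIGNIFICANT
    if (os_null and e.qol_reported) or e.toxicity_increased:
        return -1
    return 0


def oracle_survival_final(record: TrialRecord) -> tuple[Form, int, int]:
    """(form, preliminary, final) for a record gradable on form 2a/2b."""
    form = oracle_form(record)
    if form is Form.F2A:
        s = record.endpoint(Endpoint.OS)
        prelim = oracle_os_preliminary(s.control_median, s.gain, s.hr_ci.lower)
    else:
        s = record.endpoint(Endpoint.PFS)
        prelim = oracle_pfs_preliminary(s.control_median, s.gain, s.hr_ci.lower)
    final = prelim + oracle_adjustment(record, form)
    final = max(1, min(5, final))
    return form, prelim, final
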