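"""Eligibility pipeline: which trial records may be graded at all.

Mirrors a systematic-review workflow: records are first categorised
(category I — large phase-III RCTs in the target population with an
adequate comparator and an OS/PFS primary endpoint; category II — other
studies potentially scorable; category III — not eligible), then passed
through a gradeability gate that admits only randomised comparisons with a
statistically significant, multiplicity-controlled benefit of the study arm.

Comparator adequacy is setting-specific.  In platinum-sensitive disease a
platinum-based control is required (non-platinum chemotherapy is an inferior
control there); in platinum-resistant disease any guideline-listed option
is acceptable; for maintenance after response to platinum the control must
be placebo / no further treatment.  The class of the control arm is a
curated annotation on the record — this module only applies the rule to it.
"""

from __future__ import annotations

import enum
from typing import Iterable, Mapping, Optional, Sequence

from pydantic import BaseModel, Field

from .records import (
    Design,
    Endpoint,
    ComparatorClass,
    PrimaryEndpoint,
    Setting,
    Significance,
    TrialRecord,
)


class Category(str, enum.Enum):
    I = "I"
    II = "II"
    III = "III"


class ScreeningDecision(BaseModel):
    """Outcome of screening one record: category, inclusion, reasons."""

    trial_id: str
    category: Category
    included: bool
    reasons: list[str] = Field(default_factory=list)


class MissingAnnotationError(ValueError):
    """Comparator-class annotation absent where the adequacy rule needs it."""


#: Which comparator classes count as adequate, per setting.
_ADEQUATE_BY_SETTING = {
    Setting.PLATINUM_SENSITIVE: {ComparatorClass.PLATINUM_BASED},
    Setting.PLATINUM_RESISTANT: {
        ComparatorClass.GUIDELINE_LISTED,
        ComparatorClass.PLATINUM_BASED,
    },
    Setting.MAINTENANCE: {ComparatorClass.PLACEBO_OR_NO_TREATMENT},
}


def comparator_is_adequate(record: TrialRecord) -> bool:
    """Apply the setting-specific comparator rule to the curated annotation."""
    if record.comparator_class is None:
        raise MissingAnnotationError(
            f"{record.trial_id}: comparator_class annotation missing; "
            "curate the control arm before screening"
        )
    return record.comparator_class in _ADEQUATE_BY_SETTING[record.setting]


def categorise(record: TrialRecord) -> Category:
    """Assign the screening category.

    Category I requires a phase-III randomised design, an adequate
    comparator and an OS or PFS primary endpoint.  Non-randomised designs
    are category III; everything else (randomised phase II, non-inferiority
    or response-rate primaries, inadequate comparators) is category II.
    """
    if record.design is Design.OTHER:
        return Category.III
    if (
        record.design is Design.PHASE3_RCT
        and record.comparator_adequate
        and record.primary_endpoint in (PrimaryEndpoint.OS, PrimaryEndpoint.PFS)
    ):
        return Category.I
    return Category.II


def _primary_summary_kind(record: TrialRecord) -> Optional[Endpoint]:
    """Endpoint summary kind carrying the primary result.

    A non-inferiority comparison is tested on PFS in this corpus; a
    QoL/toxicity primary has no survival summary to interrogate.
    """
    mapping = {
        PrimaryEndpoint.OS: Endpoint.OS,
        PrimaryEndpoint.PFS: Endpoint.PFS,
        PrimaryEndpoint.ORR: Endpoint.ORR,
        PrimaryEndpoint.NONINFERIORITY: Endpoint.PFS,
        PrimaryEndpoint.QOL_TOX: Endpoint.QOL_TOX,
    }
    return mapping[record.primary_endpoint]


def gradeability_gate(record: TrialRecord) -> ScreeningDecision:
    """Decide whether a record may be graded, with explicit reasons.

    Included iff the record is category I/II, was not terminated early or
    superseded by a higher-quality trial, has an adequate comparator, is
    not a non-prespecified subgroup analysis, and its primary endpoint (or
    a confirmed secondary OS result) shows a statistically significant
    benefit of the study arm.
    """
    category = categorise(record)
    reasons: list[str] = []
    if category is Category.III:
        reasons.append("category III: design not eligible for scoring")
    if record.terminated_early:
        reasons.append("trial terminated prematurely")
    if record.superseded:
        reasons.append("superseded by a higher-quality trial of the same treatment")
    if not record.comparator_adequate:
        reasons.append("inadequate comparator for this setting")
    if record.subgroup_of is not None and not record.subgroup_prespecified:
        reasons.append("subgroup analysis not prespecified (exploratory); reported, not graded")

    primary = record.endpoint(_primary_summary_kind(record))
    os_summary = record.endpoint(Endpoint.OS)
    if primary is not None and primary.significant is Significance.CONFIRMED:
        pass  # significant primary benefit
    elif os_summary is not None and os_summary.significant is Significance.CONFIRMED:
        pass  # confirmed secondary OS benefit
    elif primary is not None and primary.significant is Significance.NOT_SIGNIFICANT:
        reasons.append("primary result not significant")
    else:
        reasons.append("primary endpoint result unreported or exploratory")

    return ScreeningDecision(
        trial_id=record.trial_id,
        category=category,
        included=not reasons,
        reasons=reasons,
    )


def subgroup_admissible(parent: TrialRecord, subgroups: Sequence[TrialRecord]) -> bool:
    """At most three prespecified subgroups of one trial may be graded.

    Every submitted subgroup must reference ``parent``; a dangling
    reference is a curation error and raises.
    """
    for sg in subgroups:
        if sg.subgroup_of != parent.trial_id:
            raise ValueError(
                f"{sg.trial_id}: subgroup_of={sg.subgroup_of!r} does not reference "
                f"parent {parent.trial_id!r}"
            )
    return len(subgroups) <= 3 and all(sg.subgroup_prespecified for sg in subgroups)


def screen_all(records: Sequence[TrialRecord]) -> dict[str, ScreeningDecision]:
    """Screen a corpus, enforcing the subgroup-count rule across rows.

    Non-prespecified subgroup rows are excluded individually by the gate;
    the ≤3 cap is then applied to the remaining prespecified set of each
    parent (a parent with more than three prespecified subgroup rows has
    all of them excluded, with the multiplicity caveat recorded).
    """
    by_id = {r.trial_id: r for r in records}
    decisions: dict[str, ScreeningDecision] = {}
    prespecified_counts: dict[str, int] = {}
    for record in records:
        if record.subgroup_of is not None:
            if record.subgroup_of not in by_id:
                raise ValueError(
                    f"{record.trial_id}: dangling subgroup_of reference "
                    f"{record.subgroup_of!r}"
                )
            if record.subgroup_prespecified:
                prespecified_counts[record.subgroup_of] = (
                    prespecified_counts.get(record.subgroup_of, 0) + 1
                )
    for record in records:
        decision = gradeability_gate(record)
        if (
            record.subgroup_of is not None
            and prespecified_counts.get(record.subgroup_of, 0) > 3
        ):
            decision.included = False
            decision.reasons = decision.reasons + [
                "more than three prespecified subgroups: multiplicity cap exceeded"
            ]
        decisions[record.trial_id] = decision
    return decisions
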