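"""Grading engine: form selection, threshold tables, adjustment, composition."""

import pytest

from esmo_mcbs import (
    ConfidenceInterval,
    Endpoint,
    EndpointSummary,
    EvidenceFlags,
    Form,
    MissingFieldError,
    NotGradableError,
    PrimaryEndpoint,
    Significance,
    compute_adjustment,
    grade_form_2a,
    grade_form_2b,
    grade_form_2c,
    grade_form_3,
    grade_trial,
    select_form,
)


def _summary(kind, control, gain, lower, upper=None, sig=Significance.CONFIRMED):
    upper = upper if upper is not None else round(lower + 0.3, 2)
    return EndpointSummary(
        endpoint=kind,
        control_median=control,
        gain=gain,
        hazard_ratio=round((lower + upper) / 2, 3),
        hr_ci=ConfidenceInterval(lower=lower, upper=upper),
        significant=sig,
    )


# ---------------------------------------------------------------- form choice

def test_os_primary_selects_form_2a(records_by_id):
    assert select_form(records_by_id["icon4"]) is Form.F2A


def test_pfs_primary_with_confirmed_os_selects_form_2a(records_by_id):
    assert select_form(records_by_id["adavosertib"]) is Form.F2A


def test_pfs_primary_with_null_os_selects_form_2b(records_by_id):
    assert select_form(records_by_id["oceans"]) is Form.F2B


def test_pfs_primary_with_exploratory_os_selects_form_2b(records_by_id):
    # an uncorrected, exploratory OS result never promotes to form 2a
    assert select_form(records_by_id["carbo_pld_bev"]) is Form.F2B


def test_noninferiority_selects_form_2c(records_by_id):
    assert select_form(records_by_id["calypso"]) is Form.F2C


def test_orr_primary_selects_form_3(records_by_id):
    assert select_form(records_by_id["topotecan_orr"]) is Form.F3


# ---------------------------------------------------------------- form 2a

@pytest.mark.parametrize(
    "control, gain, lower, expected",
    [
        (24, 5, 0.69, 4),      # long-survival stratum, both criteria met
        (7.2, 4.2, 0.35, 4),   # short-survival stratum
        (10, 1.0, 0.30, 1),    # gain below every band
        (24, 4.9, 0.70, 3),    # gain just under the top band
        (12, 2.5, 0.65, 3),    # control exactly at the stratum bound -> <=12 rules
        (12.1, 2.5, 0.65, 2),  # just over the bound -> >12 rules, grade-3 band needs 3 months
        (24, 5, 0.71, 2),      # HR bound misses 4/3 bands; gain never demotes below 2
        (24, 1.4, 0.30, 1),
        (3, 3.0, 0.65, 4),     # both bounds inclusive at equality
        (3, 3.0, 0.66, 2),     # 0.65 band missed; 0.70 band still reached
    ],
)
def test_form_2a_threshold_table(control, gain, lower, expected):
    assert grade_form_2a(_summary(Endpoint.OS, control, gain, lower)) == expected


# ---------------------------------------------------------------- form 2b

@pytest.mark.parametrize(
    "control, gain, lower, expected",
    [
        (8.4, 4.0, 0.39, 3),
        (11.7, 1.7, 0.68, 1),
        (8.7, 2.3, 0.44, 2),
        (3.4, 3.3, 0.38, 3),
        (5.8, 1.5, 0.65, 3),   # both boundaries exactly met -> inclusive
        (6.0, 1.5, 0.65, 3),   # control exactly at the stratum bound -> <=6 rules
        (6.1, 1.5, 0.65, 2),   # just over the bound: gain must reach 3
        (5.8, 0.5, 0.60, 2),
        (5.8, 14.0, 0.66, 1),  # HR bound failed: no gain rescues form 2b
    ],
)
def test_form_2b_threshold_table(control, gain, lower, expected):
    assert grade_form_2b(_summary(Endpoint.PFS, control, gain, lower)) == expected


def test_form_2b_never_exceeds_three():
    huge = _summary(Endpoint.PFS, 3.0, 30.0, 0.10)
    assert grade_form_2b(huge) == 3


def test_missing_field_is_named():
    incomplete = EndpointSummary(endpoint=Endpoint.OS, control_median=10.0)
    with pytest.raises(MissingFieldError, match="gain"):
        grade_form_2a(incomplete)


# ---------------------------------------------------------------- form 2c

def test_form_2c_subscale_and_discontinuation_score_three(records_by_id):
    assert grade_form_2c(records_by_id["calypso"]) == 3


def test_form_2c_global_qol_improvement_scores_four(records_by_id):
    record = records_by_id["calypso"].model_copy(deep=True)
    record.evidence = EvidenceFlags(qol_reported=True, qol_global_improved=True)
    assert grade_form_2c(record) == 4


def test_form_2c_noninferiority_alone_scores_two(records_by_id):
    record = records_by_id["calypso"].model_copy(deep=True)
    record.evidence = EvidenceFlags(qol_reported=True)
    assert grade_form_2c(record) == 2


def test_form_2c_without_any_basis_is_not_gradable(records_by_id):
    record = records_by_id["calypso"].model_copy(deep=True)
    record.evidence = EvidenceFlags()
    record.endpoint(Endpoint.PFS).significant = Significance.NOT_SIGNIFICANT
    with pytest.raises(NotGradableError):
        grade_form_2c(record)


# ---------------------------------------------------------------- form 3

@pytest.mark.parametrize("pct, expected", [(21, 2), (19.9, 1), (20, 2), (60, 3), (59.9, 2)])
def test_form_3_response_rate_bands(pct, expected):
    summary = EndpointSummary(endpoint=Endpoint.ORR, orr_pct=pct)
    assert grade_form_3(summary) == expected


def test_form_3_missing_orr_is_an_error():
    with pytest.raises(MissingFieldError, match="orr"):
        grade_form_3(EndpointSummary(endpoint=Endpoint.PFS))


# ---------------------------------------------------------------- adjustment

def test_prespecified_subscale_improvement_upgrades(records_by_id):
    assert compute_adjustment(Form.F2B, 3, records_by_id["aurelia"]) == 1


def test_null_os_without_qol_benefit_downgrades(records_by_id):
    assert compute_adjustment(Form.F2B, 3, records_by_id["oceans"]) == -1
    assert compute_adjustment(Form.F2B, 2, records_by_id["icon6"]) == -1


def test_unpublished_os_suspends_the_downgrade(records_by_id):
    assert compute_adjustment(Form.F2B, 3, records_by_id["nova_gbrca"]) == 0
    assert compute_adjustment(Form.F2B, 3, records_by_id["mito16b"]) == 0


def test_exploratory_os_suspends_the_downgrade(records_by_id):
    assert compute_adjustment(Form.F2B, 1, records_by_id["carbo_pld_bev"]) == 0


def test_offsetting_evidence_is_a_wash(records_by_id):
    record = records_by_id["oceans"].model_copy(deep=True)
    record.evidence = EvidenceFlags(
        qol_reported=True, qol_subscale_improved=True, toxicity_increased=True
    )
    assert compute_adjustment(Form.F2B, 3, record) == 0


def test_form_2a_upgrades_but_never_downgrades(records_by_id):
    record = records_by_id["icon4"].model_copy(deep=True)
    assert compute_adjustment(Form.F2A, 4, record) == 0
    record.evidence = EvidenceFlags(qol_reported=True, qol_global_improved=True)
    assert compute_adjustment(Form.F2A, 4, record) == 1
    record.evidence = EvidenceFlags(qol_reported=True, toxicity_increased=True)
    assert compute_adjustment(Form.F2A, 4, record) == 0


def test_forms_2c_and_3_take_no_adjustment(records_by_id):
    assert compute_adjustment(Form.F2C, 3, records_by_id["calypso"]) == 0
    assert compute_adjustment(Form.F3, 2, records_by_id["topotecan_orr"]) == 0


# ---------------------------------------------------------------- grade_trial

def test_grade_trial_composes_the_pipeline(records_by_id):
    result = grade_trial(records_by_id["solo2"])
    assert (result.form, result.preliminary, result.adjustment, result.final) == (
        Form.F2B, 3, -1, 2,
    )
    assert result.rationale  # every grade carries its audit trail


def test_grade_trial_without_os_keeps_preliminary(records_by_id):
    result = grade_trial(records_by_id["mito16b"])
    assert (result.form, result.final) == (Form.F2B, 3)


def test_grade_trial_not_graded_when_gate_fails(records_by_id):
    result = grade_trial(records_by_id["gog0213"])
    assert result.form is Form.NOT_GRADED
    assert result.final is None and result.preliminary is None
    assert any("not significant" in line for line in result.rationale)


def test_grade_five_reachable_via_form_2a_upgrade(records_by_id):
    record = records_by_id["icon4"].model_copy(deep=True)
    record.evidence = EvidenceFlags(qol_reported=True, qol_global_improved=True)
    result = grade_trial(record)
    assert (result.preliminary, result.adjustment, result.final) == (4, 1, 5)


def test_final_clamped_at_one(records_by_id):
    record = records_by_id["carbo_pld_bev"].model_copy(deep=True)
    # publish a null OS with QoL reported and no benefit: downgrade fires at grade 1
    record.endpoint(Endpoint.OS).significant = Significance.NOT_SIGNIFICANT
    record.evidence = EvidenceFlags(qol_reported=True)
    result = grade_trial(record)
    assert (result.preliminary, result.adjustment, result.final) == (1, -1, 1)
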