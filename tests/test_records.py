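"""Record model: validation totality, CSV/JSON round trips, schema errors."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from esmo_mcbs import (
    ConfidenceInterval,
    Design,
    Endpoint,
    EndpointSummary,
    EvidenceFlags,
    Form,
    GradedResult,
    PrimaryEndpoint,
    SchemaError,
    Setting,
    Significance,
    TrialRecord,
    read_graded,
    read_trials,
    validate_record,
    write_graded,
    write_trials,
)
from esmo_mcbs.records import CSV_COLUMNS
from esmo_mcbs.simulate import generate_trials


def test_well_formed_record_has_no_violations(records_by_id):
    assert validate_record(records_by_id["icon4"]) == []


def test_every_corpus_record_validates(corpus_records):
    for record in corpus_records:
        assert validate_record(record) == [], record.trial_id


def test_inverted_confidence_interval_is_reported(records_by_id):
    record = records_by_id["icon4"].model_copy(deep=True)
    record.endpoint(Endpoint.OS).hr_ci = ConfidenceInterval(lower=0.97, upper=0.69)
    violations = validate_record(record)
    assert len(violations) == 1
    assert "ordering" in violations[0] and "hr_ci" in violations[0]


def test_duplicate_endpoint_kind_is_reported(records_by_id):
    record = records_by_id["solo2"].model_copy(deep=True)
    record.endpoints = record.endpoints + [record.endpoints[0].model_copy(deep=True)]
    violations = validate_record(record)
    assert any("duplicate" in v for v in violations)


def test_qol_improvement_without_reporting_is_reported(records_by_id):
    record = records_by_id["mito16b"].model_copy(deep=True)
    record.evidence = EvidenceFlags(qol_reported=False, qol_global_improved=True)
    assert any("qol_reported" in v for v in validate_record(record))


@settings(derandomize=True, max_examples=150)
@given(
    lower=st.floats(allow_nan=True, allow_infinity=True),
    upper=st.floats(allow_nan=True, allow_infinity=True),
    gain=st.floats(allow_nan=True, allow_infinity=True) | st.none(),
    control=st.floats(allow_nan=True, allow_infinity=True) | st.none(),
    hr=st.floats(allow_nan=True, allow_infinity=True) | st.none(),
    orr=st.floats(allow_nan=True, allow_infinity=True) | st.none(),
    n=st.integers(-10, 10_000),
)
def test_validate_record_is_total(lower, upper, gain, control, hr, orr, n):
    """validate_record never raises, whatever numbers the fields hold."""
    record = TrialRecord(
        trial_id="fuzz",
        setting=Setting.PLATINUM_RESISTANT,
        design=Design.PHASE2_RCT,
        n=n,
        experimental_label="x",
        comparator_label="y",
        primary_endpoint=PrimaryEndpoint.PFS,
        endpoints=[
            EndpointSummary(
                endpoint=Endpoint.PFS,
                control_median=control,
                gain=gain,
                hazard_ratio=hr,
                hr_ci=ConfidenceInterval(lower=lower, upper=upper),
                orr_pct=orr,
            )
        ],
    )
    violations = validate_record(record)
    assert isinstance(violations, list)
    assert all(isinstance(v, str) and v for v in violations)


@pytest.mark.parametrize("fmt", ["csv", "json"])
@pytest.mark.parametrize("seed", [0, 7])
def test_round_trip_is_identity_on_generated_records(tmp_path, fmt, seed):
    records = generate_trials(seed=seed, n_trials=60)
    path = tmp_path / f"trials.{fmt}"
    write_trials(records, path, format=fmt)
    assert read_trials(path, format=fmt) == records


def test_round_trip_is_identity_on_corpus(tmp_path, corpus_records):
    path = tmp_path / "corpus.csv"
    write_trials(corpus_records, path, format="csv")
    assert read_trials(path, format="csv") == corpus_records


def test_absent_distinguished_from_zero(tmp_path, records_by_id):
    """An unreported OS gain must not collapse to 0.0 across a round trip."""
    nova = records_by_id["nova_gbrca"]
    carbo = records_by_id["carbo_topotecan"]
    path = tmp_path / "t.csv"
    write_trials([nova, carbo], path)
    back = read_trials(path)
    assert back[0].endpoint(Endpoint.OS) is None
    assert back[1].endpoint(Endpoint.PFS).gain == 0.0


def test_empty_csv_with_header_only(tmp_path):
    path = tmp_path / "empty.csv"
    path.write_text(",".join(CSV_COLUMNS) + "\n", encoding="utf-8")
    assert read_trials(path) == []


def test_unknown_enum_value_names_admissible_values(tmp_path, records_by_id):
    path = tmp_path / "bad.csv"
    write_trials([records_by_id["icon4"]], path)
    text = path.read_text(encoding="utf-8").replace("platinum_sensitive", "weird")
    path.write_text(text, encoding="utf-8")
    with pytest.raises(SchemaError, match="admissible.*platinum_sensitive"):
        read_trials(path)


def test_header_mismatch_is_an_error(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("a,b,c\n1,2,3\n", encoding="utf-8")
    with pytest.raises(SchemaError, match="header"):
        read_trials(path)


def test_malformed_number_names_row_and_column(tmp_path, records_by_id):
    path = tmp_path / "bad.csv"
    write_trials([records_by_id["icon4"]], path)
    path.write_text(path.read_text(encoding="utf-8").replace("0.69", "abc"), encoding="utf-8")
    with pytest.raises(SchemaError, match="row 1.*os_hr_lo"):
        read_trials(path)


@pytest.mark.parametrize("fmt", ["csv", "json"])
def test_graded_results_round_trip(tmp_path, fmt, corpus_records):
    from esmo_mcbs import grade_all

    results = grade_all(corpus_records)
    path = tmp_path / f"graded.{fmt}"
    write_graded(results, path, format=fmt)
    back = read_graded(path, format=fmt)
    assert back == results
    # rationale must be preserved verbatim
    assert all(a.rationale == b.rationale for a, b in zip(results, back))


def test_write_graded_row_count(tmp_path):
    results = [
        GradedResult(trial_id=f"t{i}", form=Form.F2B, preliminary=3, adjustment=0,
                     final=3, rationale=["r"])
        for i in range(19)
    ]
    path = tmp_path / "g.csv"
    write_graded(results, path, format="csv")
    lines = path.read_text(encoding="utf-8").strip().splitlines()
    assert len(lines) == 20  # header + 19 data rows


def test_write_graded_empty_list_is_header_only(tmp_path):
    path = tmp_path / "g.csv"
    write_graded([], path, format="csv")
    assert len(path.read_text(encoding="utf-8").strip().splitlines()) == 1
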