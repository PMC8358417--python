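"""Domain types and CSV/JSON serialization for curated trial records.

The package works on *published summary statistics* of randomised trials in
recurrent epithelial ovarian cancer — control-arm medians in months, absolute
median gains, hazard ratios with 95% confidence intervals, objective response
rates — exactly as printed in trial reports, never on patient-level data.

Two conventions matter throughout:

* **Absent is not zero.**  An overall-survival gain that was never reported
  is encoded as ``None`` (``""`` in CSV), because the quality-of-life /
  toxicity adjustment of the ESMO-MCBS is *suspended* while OS data are
  unpublished but *applies* once a null OS result is in print.
* **Validation never raises.**  Records are permissive containers;
  :func:`validate_record` returns a list of human-readable violations so a
  curation error in one row cannot take down a batch run.
"""

from __future__ import annotations

import csv
import enum
import json
import math
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from pydantic import BaseModel, ConfigDict, Field


class Endpoint(str, enum.Enum):
    """Endpoint kinds a trial row can summarise."""

    OS = "os"
    PFS = "pfs"
    ORR = "orr"
    QOL_TOX = "qol_tox"


class PrimaryEndpoint(str, enum.Enum):
    """Primary endpoint declared by the trial (drives evaluation-form choice)."""

    OS = "os"
    PFS = "pfs"
    ORR = "orr"
    QOL_TOX = "qol_tox"
    NONINFERIORITY = "noninferiority"


class Setting(str, enum.Enum):
    """Treatment setting within recurrent ovarian cancer."""

    PLATINUM_SENSITIVE = "platinum_sensitive"
    MAINTENANCE = "maintenance"
    PLATINUM_RESISTANT = "platinum_resistant"


class Design(str, enum.Enum):
    PHASE3_RCT = "phase3_rct"
    PHASE2_RCT = "phase2_rct"
    OTHER = "other"


class Significance(str, enum.Enum):
    """Tri-state significance status of an endpoint result.

    ``CONFIRMED`` means a statistically significant *benefit of the study
    arm* under the trial's prespecified, multiplicity-controlled test.  An
    exploratory analysis that was not corrected for multiple testing is
    never ``CONFIRMED``, however small its p-value.
    """

    CONFIRMED = "confirmed"
    NOT_SIGNIFICANT = "not_significant"
    EXPLORATORY_OR_UNREPORTED = "exploratory_or_unreported"


class Form(str, enum.Enum):
    """ESMO-MCBS palliative evaluation forms (plus the not-graded outcome)."""

    F2A = "2a"
    F2B = "2b"
    F2C = "2c"
    F3 = "3"
    NOT_GRADED = "not_graded"


class ComparatorClass(str, enum.Enum):
    """Curated annotation of what the control arm is, for the adequacy rule."""

    PLATINUM_BASED = "platinum_based"
    GUIDELINE_LISTED = "guideline_listed"
    PLACEBO_OR_NO_TREATMENT = "placebo_or_no_treatment"
    OTHER = "other"


class ConfidenceInterval(BaseModel):
    """A 95% confidence interval for a (dimensionless) hazard ratio."""

    model_config = ConfigDict(frozen=True)

    lower: float
    upper: float


class EndpointSummary(BaseModel):
    """Published summary of one endpoint of one trial (or subgroup) row."""

    model_config = ConfigDict(validate_assignment=True)

    endpoint: Endpoint
    control_median: Optional[float] = None  # months
    gain: Optional[float] = None  # months, may be negative
    hazard_ratio: Optional[float] = None
    hr_ci: Optional[ConfidenceInterval] = None
    orr_pct: Optional[float] = None
    significant: Significance = Significance.EXPLORATORY_OR_UNREPORTED


class EvidenceFlags(BaseModel):
    """Quality-of-life / toxicity evidence driving the ±1 adjustment.

    ``qol_subscale_improved`` is reserved for *prespecified* subscale
    analyses (the only kind the scale credits).
    """

    model_config = ConfigDict(validate_assignment=True)

    qol_reported: bool = False
    qol_global_improved: bool = False
    qol_subscale_improved: bool = False
    toxicity_reduced: bool = False
    toxicity_increased: bool = False
    early_discontinuation_reduced: bool = False

    @property
    def any_qol_or_toxicity_benefit(self) -> bool:
        return (
            self.qol_global_improved
            or self.qol_subscale_improved
            or self.toxicity_reduced
        )


class TrialRecord(BaseModel):
    """One trial — or one prespecified subgroup row of a trial.

    A trial whose table row fans out into subgroup analyses (ITT / gBRCA /
    HRD …) is stored as one parent record plus one record per subgroup with
    ``subgroup_of`` pointing at the parent, mirroring the row structure of
    the source tables: each row carries its own grade.
    """

    model_config = ConfigDict(validate_assignment=True)

    trial_id: str
    study_name: Optional[str] = None
    setting: Setting
    design: Design
    n: int
    experimental_label: str
    comparator_label: str
    primary_endpoint: PrimaryEndpoint
    endpoints: list[EndpointSummary] = Field(default_factory=list)
    evidence: EvidenceFlags = Field(default_factory=EvidenceFlags)
    subgroup_of: Optional[str] = None
    subgroup_prespecified: bool = False
    comparator_adequate: bool = True
    terminated_early: bool = False
    superseded: bool = False
    comparator_class: Optional[ComparatorClass] = None

    def endpoint(self, kind: Union[Endpoint, str]) -> Optional[EndpointSummary]:
        """Return the summary for ``kind`` or None when not reported."""
        kind = Endpoint(kind)
        for summary in self.endpoints:
            if summary.endpoint is kind:
                return summary
        return None


class GradedResult(BaseModel):
    """Outcome of grading one record: form, preliminary, adjustment, final.

    ``form == NOT_GRADED`` iff ``final is None``; the rationale lists every
    rule that fired, in order, so a grade is auditable back to the inputs.
    """

    model_config = ConfigDict(validate_assignment=True)

    trial_id: str
    form: Form
    preliminary: Optional[int] = None
    adjustment: int = 0
    final: Optional[int] = None
    rationale: list[str] = Field(default_factory=list)

    @property
    def substantial_benefit(self) -> bool:
        """Grades 4-5 denote substantial clinical benefit on the scale."""
        return self.final is not None and self.final >= 4


# --------------------------------------------------------------------------
# validation


def _finite(x: Optional[float]) -> bool:
    return x is None or (isinstance(x, (int, float)) and math.isfinite(x))


def validate_record(record: TrialRecord) -> list[str]:
    """Check every domain invariant; return violations, never raise.

    Each violation names the offending field and the rule it breaks.
    """
    v: list[str] = []
    if record.n < 1:
        v.append(f"n: must be >= 1, got {record.n}")
    if not record.trial_id:
        v.append("trial_id: must be non-empty")

    seen: set[Endpoint] = set()
    for s in record.endpoints:
        tag = f"endpoints[{s.endpoint.value}]"
        if s.endpoint in seen:
            v.append(f"{tag}: duplicate endpoint kind")
        seen.add(s.endpoint)
        for name in ("control_median", "gain", "hazard_ratio", "orr_pct"):
            if not _finite(getattr(s, name)):
                v.append(f"{tag}.{name}: must be a finite number")
        if s.control_median is not None and _finite(s.control_median) and s.control_median < 0:
            v.append(f"{tag}.control_median: must be >= 0 months")
        ci = s.hr_ci
        if ci is not None:
            if not (_finite(ci.lower) and _finite(ci.upper)):
                v.append(f"{tag}.hr_ci: bounds must be finite numbers")
            else:
                if ci.lower <= 0 or ci.upper <= 0:
                    v.append(f"{tag}.hr_ci: bounds must be strictly positive")
                if ci.lower > ci.upper:
                    v.append(
                        f"{tag}.hr_ci: ConfidenceInterval ordering lower <= upper "
                        f"violated ({ci.lower} > {ci.upper})"
                    )
                elif (
                    s.hazard_ratio is not None
                    and _finite(s.hazard_ratio)
                    and not (ci.lower <= s.hazard_ratio <= ci.upper)
                ):
                    v.append(
                        f"{tag}.hazard_ratio: point estimate {s.hazard_ratio} "
                        f"outside its CI ({ci.lower}-{ci.upper})"
                    )
        if s.hazard_ratio is not None and _finite(s.hazard_ratio) and s.hazard_ratio <= 0:
            v.append(f"{tag}.hazard_ratio: must be strictly positive")
        if s.endpoint is Endpoint.ORR and s.orr_pct is None:
            v.append(f"{tag}.orr_pct: required for an ORR endpoint")
        if s.orr_pct is not None and _finite(s.orr_pct) and not (0 <= s.orr_pct <= 100):
            v.append(f"{tag}.orr_pct: must lie in [0, 100]")

    e = record.evidence
    if (e.qol_global_improved or e.qol_subscale_improved) and not e.qol_reported:
        v.append("evidence.qol_reported: QoL improvement flagged but QoL not reported")
    if record.subgroup_of is not None and record.subgroup_of == record.trial_id:
        v.append("subgroup_of: record cannot be a subgroup of itself")
    return v


# --------------------------------------------------------------------------
# CSV / JSON serialization

#: Column order of the trial-record CSV dialect (UTF-8, comma separated,
#: header mandatory, "" = absent).  The two trailing columns carry the ORR
#: significance status and the curated comparator annotation.
CSV_COLUMNS = [
    "trial_id", "study_name", "setting", "design", "n",
    "experimental_label", "comparator_label", "primary_endpoint",
    "pfs_control", "pfs_gain", "pfs_hr", "pfs_hr_lo", "pfs_hr_hi", "pfs_significant",
    "os_control", "os_gain", "os_hr", "os_hr_lo", "os_hr_hi", "os_significant",
    "orr_pct",
    "qol_reported", "qol_global_improved", "qol_subscale_improved",
    "toxicity_reduced", "toxicity_increased", "early_discontinuation_reduced",
    "subgroup_of", "subgroup_prespecified", "comparator_adequate",
    "terminated_early", "superseded",
    "orr_significant", "comparator_class",
]

_BOOL_FIELDS = {
    "qol_reported", "qol_global_improved", "qol_subscale_improved",
    "toxicity_reduced", "toxicity_increased", "early_discontinuation_reduced",
    "subgroup_prespecified", "comparator_adequate", "terminated_early",
    "superseded",
}


class SchemaError(ValueError):
    """Raised when a file does not match the declared record schema."""


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, bool):
        return "true" if x else "false"
    if isinstance(x, enum.Enum):
        return x.value
    if isinstance(x, float) and x.is_integer():
        return str(int(x))
    return str(x)


def _parse_float(raw: str, row: int, col: str) -> Optional[float]:
    if raw == "":
        return None
    try:
        return float(raw)
    except ValueError:
        raise SchemaError(f"row {row}, column {col!r}: not a number: {raw!r}") from None


def _parse_bool(raw: str, row: int, col: str) -> bool:
    if raw in ("true", "1", "True"):
        return True
    if raw in ("false", "0", "False", ""):
        return False
    raise SchemaError(f"row {row}, column {col!r}: not a boolean: {raw!r}")


def _parse_enum(enum_cls, raw: str, row: int, col: str):
    try:
        return enum_cls(raw)
    except ValueError:
        admissible = ", ".join(m.value for m in enum_cls)
        raise SchemaError(
            f"row {row}, column {col!r}: unknown value {raw!r}; "
            f"admissible: {admissible}"
        ) from None


def record_to_row(record: TrialRecord) -> dict[str, str]:
    """Flatten a record onto the CSV schema (OS/PFS/ORR summaries only)."""
    row = {c: "" for c in CSV_COLUMNS}
    row.update(
        trial_id=record.trial_id,
        study_name=_fmt(record.study_name),
        setting=record.setting.value,
        design=record.design.value,
        n=str(record.n),
        experimental_label=record.experimental_label,
        comparator_label=record.comparator_label,
        primary_endpoint=record.primary_endpoint.value,
        subgroup_of=_fmt(record.subgroup_of),
        comparator_class=_fmt(record.comparator_class),
    )
    for name in _BOOL_FIELDS:
        holder = record.evidence if hasattr(record.evidence, name) else record
        row[name] = _fmt(getattr(holder, name))
    for prefix in ("pfs", "os"):
        s = record.endpoint(prefix)
        if s is None:
            continue
        row[f"{prefix}_control"] = _fmt(s.control_median)
        row[f"{prefix}_gain"] = _fmt(s.gain)
        row[f"{prefix}_hr"] = _fmt(s.hazard_ratio)
        if s.hr_ci is not None:
            row[f"{prefix}_hr_lo"] = _fmt(s.hr_ci.lower)
            row[f"{prefix}_hr_hi"] = _fmt(s.hr_ci.upper)
        row[f"{prefix}_significant"] = s.significant.value
    orr = record.endpoint(Endpoint.ORR)
    if orr is not None:
        row["orr_pct"] = _fmt(orr.orr_pct)
        row["orr_significant"] = orr.significant.value
    return row


def row_to_record(row: dict[str, str], index: int = 0) -> TrialRecord:
    """Parse one CSV row (string-valued dict) into a TrialRecord."""
    endpoints: list[EndpointSummary] = []
    for prefix, kind in (("pfs", Endpoint.PFS), ("os", Endpoint.OS)):
        fields = {
            "control_median": _parse_float(row[f"{prefix}_control"], index, f"{prefix}_control"),
            "gain": _parse_float(row[f"{prefix}_gain"], index, f"{prefix}_gain"),
            "hazard_ratio": _parse_float(row[f"{prefix}_hr"], index, f"{prefix}_hr"),
        }
        lo = _parse_float(row[f"{prefix}_hr_lo"], index, f"{prefix}_hr_lo")
        hi = _parse_float(row[f"{prefix}_hr_hi"], index, f"{prefix}_hr_hi")
        ci = ConfidenceInterval(lower=lo, upper=hi) if lo is not None and hi is not None else None
        sig_raw = row[f"{prefix}_significant"]
        has_any = any(x is not None for x in fields.values()) or ci is not None or sig_raw != ""
        if has_any:
            sig = (
                _parse_enum(Significance, sig_raw, index, f"{prefix}_significant")
                if sig_raw
                else Significance.EXPLORATORY_OR_UNREPORTED
            )
            endpoints.append(EndpointSummary(endpoint=kind, hr_ci=ci, significant=sig, **fields))
    orr_pct = _parse_float(row["orr_pct"], index, "orr_pct")
    if orr_pct is not None or row["orr_significant"] != "":
        sig = (
            _parse_enum(Significance, row["orr_significant"], index, "orr_significant")
            if row["orr_significant"]
            else Significance.EXPLORATORY_OR_UNREPORTED
        )
        endpoints.append(EndpointSummary(endpoint=Endpoint.ORR, orr_pct=orr_pct, significant=sig))

    evidence = EvidenceFlags(
        **{
            name: _parse_bool(row[name], index, name)
            for name in _BOOL_FIELDS
            if name in EvidenceFlags.model_fields
        }
    )
    try:
        n = int(row["n"])
    except ValueError:
        raise SchemaError(f"row {index}, column 'n': not an integer: {row['n']!r}") from None
    return TrialRecord(
        trial_id=row["trial_id"],
        study_name=row["study_name"] or None,
        setting=_parse_enum(Setting, row["setting"], index, "setting"),
        design=_parse_enum(Design, row["design"], index, "design"),
        n=n,
        experimental_label=row["experimental_label"],
        comparator_label=row["comparator_label"],
        primary_endpoint=_parse_enum(
            PrimaryEndpoint, row["primary_endpoint"], index, "primary_endpoint"
        ),
        endpoints=endpoints,
        evidence=evidence,
        subgroup_of=row["subgroup_of"] or None,
        subgroup_prespecified=_parse_bool(row["subgroup_prespecified"], index, "subgroup_prespecified"),
        comparator_adequate=_parse_bool(row["comparator_adequate"], index, "comparator_adequate"),
        terminated_early=_parse_bool(row["terminated_early"], index, "terminated_early"),
        superseded=_parse_bool(row["superseded"], index, "superseded"),
        comparator_class=(
            _parse_enum(ComparatorClass, row["comparator_class"], index, "comparator_class")
            if row.get("comparator_class")
            else None
        ),
    )


def read_trials(path: Union[str, Path], format: str = "csv") -> list[TrialRecord]:
    """Read trial records from CSV or JSON.

    CSV must carry exactly the :data:`CSV_COLUMNS` header; JSON is a list of
    record objects with the same field names (nested, as produced by
    :func:`write_trials`).
    """
    path = Path(path)
    if format == "json":
        data = json.loads(path.read_text(encoding="utf-8"))
        return [TrialRecord.model_validate(obj) for obj in data]
    if format != "csv":
        raise ValueError(f"unknown format {format!r}; admissible: csv, json")
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, header row required")
        if list(reader.fieldnames) != CSV_COLUMNS:
            raise SchemaError(
                f"{path}: header mismatch; expected {CSV_COLUMNS}, got {list(reader.fieldnames)}"
            )
        return [row_to_record(row, i) for i, row in enumerate(reader, start=1)]


def write_trials(records: Sequence[TrialRecord], path: Union[str, Path], format: str = "csv") -> None:
    """Write records to CSV or JSON; lossless round trip with read_trials."""
    path = Path(path)
    if format == "json":
        payload = [r.model_dump(mode="json") for r in records]
        path.write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")
        return
    if format != "csv":
        raise ValueError(f"unknown format {format!r}; admissible: csv, json")
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS)
        writer.writeheader()
        for record in records:
            writer.writerow(record_to_row(record))


GRADED_COLUMNS = ["trial_id", "form", "preliminary", "adjustment", "final", "rationale"]
_RATIONALE_SEP = " ;; "  # never produced by the engine's rationale strings


def write_graded(results: Sequence[GradedResult], path: Union[str, Path], format: str = "csv") -> None:
    """Write graded results; the rationale trace is preserved verbatim."""
    path = Path(path)
    if format == "json":
        payload = [r.model_dump(mode="json") for r in results]
        path.write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")
        return
    if format != "csv":
        raise ValueError(f"unknown format {format!r}; admissible: csv, json")
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=GRADED_COLUMNS)
        writer.writeheader()
        for r in results:
            writer.writerow(
                {
                    "trial_id": r.trial_id,
                    "form": r.form.value,
                    "preliminary": _fmt(r.preliminary),
                    "adjustment": str(r.adjustment),
                    "final": _fmt(r.final),
                    "rationale": _RATIONALE_SEP.join(r.rationale),
                }
            )


def read_graded(path: Union[str, Path], format: str = "csv") -> list[GradedResult]:
    """Inverse of :func:`write_graded`."""
    path = Path(path)
    if format == "json":
        data = json.loads(path.read_text(encoding="utf-8"))
        return [GradedResult.model_validate(obj) for obj in data]
    if format != "csv":
        raise ValueError(f"unknown format {format!r}; admissible: csv, json")
    out: list[GradedResult] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if list(reader.fieldnames or []) != GRADED_COLUMNS:
            raise SchemaError(f"{path}: header mismatch for graded-results file")
        for i, row in enumerate(reader, start=1):
            out.append(
                GradedResult(
                    trial_id=row["trial_id"],
                    form=_parse_enum(Form, row["form"], i, "form"),
                    preliminary=int(row["preliminary"]) if row["preliminary"] else None,
                    adjustment=int(row["adjustment"]),
                    final=int(row["final"]) if row["final"] else None,
                    rationale=row["rationale"].split(_RATIONALE_SEP) if row["rationale"] else [],
                )
            )
    return out


def export_json_schema() -> dict:
    """JSON Schema for a list of trial records (generated from the models)."""
    return {
        "$schema": "https://json-schema.org/draft/2020-12/schema",
        "title": "Recurrent-ovarian-cancer trial record list",
        "type": "array",
        "items": TrialRecord.model_json_schema(),
    }
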