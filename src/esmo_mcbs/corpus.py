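"""Curated corpus of published recurrent-ovarian-cancer trial rows.

The packaged CSV fixtures transcribe the three summary tables of the
systematic review this package operationalises: 14 phase-III and 5
randomised phase-II trials with statistically significant results (with
their printed MCBS score and evaluation form, subgroup rows expanded one
record per row), and 27 randomised trials without a significant benefit,
which carry no grade.  The corpus is the normative regression suite for
the grading engine: :func:`run_corpus_check` re-grades every record and
reports any cell that disagrees with print.

Fixture files are versioned and checksummed; a mismatch means the shipped
data were edited and the corpus can no longer be trusted as transcribed.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Union

from .grading import grade_all
from .records import Form, GradedResult, Setting, TrialRecord, read_trials

#: Human-process statistics of the underlying literature search.  These are
#: reviewer metadata — they summarise manual screening of an external
#: corpus and are not computable from the packaged records.
CORPUS_METADATA = {
    "papers_screened": 1127,
    "reports_of_randomised_trials": 61,
    "original_trials_assessed": 46,
    "observer_agreement_pct": 98.0,
    "printed_patient_totals": {
        # as printed in the review's results text, per setting
        "platinum_sensitive": 5470,
        "maintenance": 3394,
        "platinum_resistant": 8137,
    },
}

TRIALS_CSV = "corpus_trials.csv"
EXPECTED_CSV = "corpus_expected.csv"

#: sha256 of the packaged fixture files (verified on load).
CHECKSUMS: dict[str, str] = {
    TRIALS_CSV: "8bbe73ad5d72d1132fbebbf7d1bdfbead33e267e098d2dc3dfc47f5cc8fbd934",
    EXPECTED_CSV: "cb8ea2d127de47c91488045028258dc5a17f0a9c0313df4ed975f11effcf96c4",
}


class ChecksumError(RuntimeError):
    """A packaged fixture file does not match its recorded checksum."""


@dataclass(frozen=True)
class FixtureEntry:
    """One corpus row: the record, the printed expectation, its provenance."""

    record: TrialRecord
    expected: GradedResult
    provenance: str


@dataclass(frozen=True)
class Mismatch:
    """A disagreement between the engine and a printed grade cell."""

    trial_id: str
    field: str
    expected: object
    actual: object


def _file_sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _data_dir() -> Path:
    return Path(str(resources.files("esmo_mcbs.data")))


def load_corpus(
    data_dir: Optional[Union[str, Path]] = None, verify: bool = True
) -> list[FixtureEntry]:
    """Load the packaged fixture corpus (or one from ``data_dir``).

    With ``verify=True`` the files must match the recorded sha256 sums.
    """
    directory = Path(data_dir) if data_dir is not None else _data_dir()
    trials_path = directory / TRIALS_CSV
    expected_path = directory / EXPECTED_CSV
    if verify:
        for path in (trials_path, expected_path):
            digest = _file_sha256(path)
            if digest != CHECKSUMS[path.name]:
                raise ChecksumError(
                    f"{path.name}: sha256 {digest} does not match the recorded "
                    f"checksum; fixture file was modified"
                )
    records = read_trials(trials_path, format="csv")
    expected: dict[str, tuple[GradedResult, str]] = {}
    with expected_path.open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            expected[row["trial_id"]] = (
                GradedResult(
                    trial_id=row["trial_id"],
                    form=Form(row["form"]),
                    preliminary=int(row["preliminary"]) if row["preliminary"] else None,
                    adjustment=int(row["adjustment"]) if row["adjustment"] else 0,
                    final=int(row["final"]) if row["final"] else None,
                    rationale=[row["provenance"]],
                ),
                row["provenance"],
            )
    entries: list[FixtureEntry] = []
    for record in records:
        if record.trial_id not in expected:
            raise KeyError(f"no expected grade row for trial {record.trial_id!r}")
        exp, provenance = expected[record.trial_id]
        entries.append(FixtureEntry(record=record, expected=exp, provenance=provenance))
    return entries


def graded_entries(entries: list[FixtureEntry]) -> list[FixtureEntry]:
    """The grade-bearing rows (printed score cells of the first two tables)."""
    return [e for e in entries if e.expected.final is not None]


def count_trials(entries: list[FixtureEntry], table: str) -> int:
    """Number of distinct trials transcribed from ``table`` (subgroups folded)."""
    return sum(
        1
        for e in entries
        if e.provenance.startswith(table) and e.record.subgroup_of is None
    )


def patients_by_setting(entries: list[FixtureEntry]) -> dict[Setting, int]:
    """Randomised patients per setting, counting each trial once (no subgroup rows)."""
    totals: dict[Setting, int] = {s: 0 for s in Setting}
    for e in entries:
        if e.record.subgroup_of is None:
            totals[e.record.setting] += e.record.n
    return totals


def run_corpus_check(entries: Optional[list[FixtureEntry]] = None) -> list[Mismatch]:
    """Re-grade the corpus and report every cell disagreeing with print.

    An empty report means the engine reproduces every printed evaluation
    form, preliminary grade, adjustment and final grade, and leaves every
    non-significant trial ungraded.  Mismatches are reported, not raised.
    """
    if entries is None:
        entries = load_corpus()
    results = {r.trial_id: r for r in grade_all([e.record for e in entries])}
    mismatches: list[Mismatch] = []
    for e in entries:
        actual = results[e.record.trial_id]
        checks = [("form", e.expected.form, actual.form), ("final", e.expected.final, actual.final)]
        if e.expected.final is not None:
            checks += [
                ("preliminary", e.expected.preliminary, actual.preliminary),
                ("adjustment", e.expected.adjustment, actual.adjustment),
            ]
        for name, want, got in checks:
            if want != got:
                mismatches.append(
                    Mismatch(trial_id=e.record.trial_id, field=name, expected=want, actual=got)
                )
    return mismatches
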