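"""CAPS-5 cohort data model, delimited-text I/O and validation.

The CAPS-5 (Clinician-Administered PTSD Scale for DSM-5) total used here is
the 20-item severity score on a 0-80 scale: each item is rated 0-4 and the
items are grouped into four symptom clusters,

====== ============================================ ===== =========
intab  cluster                                      items max score
====== ============================================ ===== =========
B      intrusion                                      5      20
C      avoidance                                      2       8
D      negative alterations in cognition and mood     7      28
E      arousal and reactivity                         6      24
====== ============================================ ===== =========

A cohort row carries one participant's arm label (active treatment or sham)
and the total plus the four cluster subtotals at three timepoints: baseline
(``pre``), end of treatment (``post``) and 3-month follow-up (``fup``).
Follow-up (or post) assessments may be missing; such records are kept in the
cohort and excluded, with a logged count, by analyses that need them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Arm",
    "CapsScores",
    "ParticipantRecord",
    "Cohort",
    "Violation",
    "ValidationReport",
    "CohortReadError",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
    "CLUSTER_ITEM_COUNTS",
    "CLUSTER_MAX",
    "COLUMNS",
]

#: number of CAPS-5 items per symptom cluster (B, C, D, E)
CLUSTER_ITEM_COUNTS = {"B": 5, "C": 2, "D": 7, "E": 6}
#: per-cluster maximum subtotal (items x 4, the top of the 0-4 item scale)
CLUSTER_MAX = {k: 4 * v for k, v in CLUSTER_ITEM_COUNTS.items()}
TOTAL_MAX = 80

TIMEPOINTS = ("pre", "post", "fup")

#: canonical cohort-file header
COLUMNS = ["participant_id", "arm"] + [
    f"{c}_{tp}" for tp in TIMEPOINTS for c in ("total", "B", "C", "D", "E")
]

#: arm labels accepted on read (case-insensitive); canonical labels written out
ARM_ALIASES = {
    "active": "ACTIVE",
    "hbot": "ACTIVE",
    "sham": "SHAM",
}


class Arm(str, Enum):
    """Trial arm: active treatment or sham control."""

    ACTIVE = "ACTIVE"
    SHAM = "SHAM"


@dataclass(frozen=True)
class CapsScores:
    """Total and cluster subtotals for one assessment."""

    total: int
    b: int
    c: int
    d: int
    e: int

    def cluster_sum(self) -> int:
        return self.b + self.c + self.d + self.e

    def as_tuple(self) -> tuple[int, int, int, int, int]:
        return (self.total, self.b, self.c, self.d, self.e)


@dataclass(frozen=True)
class ParticipantRecord:
    """One participant: arm plus scores at baseline / post / follow-up.

    ``post`` and ``fup`` may be ``None`` (missed assessment); ``pre`` is
    mandatory — a row without a baseline is rejected on read.
    """

    participant_id: str
    arm: Arm
    pre: CapsScores
    post: Optional[CapsScores] = None
    fup: Optional[CapsScores] = None

    def scores(self, timepoint: str) -> Optional[CapsScores]:
        if timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {timepoint!r}")
        return getattr(self, timepoint)

    def complete(self) -> bool:
        """True when all three assessments are present."""
        return self.post is not None and self.fup is not None


@dataclass
class Cohort:
    """Ordered collection of participant records plus provenance metadata."""

    records: list[ParticipantRecord] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def arm(self, arm: Arm | str | None) -> list[ParticipantRecord]:
        """Records in one arm, or all records when ``arm`` is None."""
        if arm is None:
            return list(self.records)
        arm = Arm(arm.upper()) if isinstance(arm, str) else arm
        return [r for r in self.records if r.arm is arm]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row: dict = {"participant_id": r.participant_id, "arm": r.arm.value}
            for tp in TIMEPOINTS:
                s = r.scores(tp)
                vals = s.as_tuple() if s is not None else (None,) * 5
                for name, v in zip(("total", "B", "C", "D", "E"), vals):
                    row[f"{name}_{tp}"] = v
            rows.append(row)
        df = pd.DataFrame(rows, columns=COLUMNS)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, metadata: dict | None = None) -> "Cohort":
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise CohortReadError(f"missing mandatory columns: {missing}")
        records = []
        problems: list[str] = []
        for idx, row in df.iterrows():
            try:
                records.append(_record_from_row(row))
            except ValueError as exc:
                problems.append(f"row {idx}: {exc}")
        if problems:
            raise CohortReadError(
                "cohort rows failed type coercion:\n  " + "\n  ".join(problems)
            )
        return cls(records=records, metadata=dict(metadata or {}))


class CohortReadError(ValueError):
    """Raised when a cohort file cannot be parsed into records."""


def _coerce_score(value, column: str) -> Optional[int]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    if isinstance(value, str):
        value = value.strip()
        if value == "":
            return None
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise ValueError(f"non-integer score {value!r} in column {column}")
    if f != int(f):
        raise ValueError(f"non-integer score {value!r} in column {column}")
    return int(f)


def _scores_from_row(row, tp: str) -> Optional[CapsScores]:
    vals = {name: _coerce_score(row[f"{name}_{tp}"], f"{name}_{tp}")
            for name in ("total", "B", "C", "D", "E")}
    present = [v is not None for v in vals.values()]
    if not any(present):
        return None
    if not all(present):
        missing = [k for k, v in vals.items() if v is None]
        raise ValueError(f"partially missing scores at {tp}: {missing}")
    return CapsScores(vals["total"], vals["B"], vals["C"], vals["D"], vals["E"])


def _record_from_row(row) -> ParticipantRecord:
    pid = str(row["participant_id"]).strip()
    if not pid or pid.lower() == "nan":
        raise ValueError("empty participant_id")
    raw_arm = str(row["arm"]).strip().lower()
    if raw_arm not in ARM_ALIASES:
        raise ValueError(f"unknown arm label {row['arm']!r}")
    arm = Arm(ARM_ALIASES[raw_arm])
    pre = _scores_from_row(row, "pre")
    if pre is None:
        raise ValueError("missing baseline (pre) scores")
    return ParticipantRecord(
        participant_id=pid,
        arm=arm,
        pre=pre,
        post=_scores_from_row(row, "post"),
        fup=_scores_from_row(row, "fup"),
    )


def read_cohort(path: str | Path, delimiter: str | None = None) -> Cohort:
    """Read a cohort table from delimited text (comma default, tab accepted).

    The header must contain all documented columns; extra columns are
    ignored. Arm labels are matched case-insensitively against the alias
    table (``HBOT`` -> ACTIVE). Rows with malformed score cells are
    enumerated in the raised :class:`CohortReadError`, never dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if delimiter is None:
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline()
        delimiter = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    cohort = Cohort.from_dataframe(df, metadata={"source": str(path), "delimiter": delimiter})
    logger.info("read %d records from %s", len(cohort), path)
    return cohort


def write_cohort(cohort: Cohort, path: str | Path, delimiter: str = ",") -> None:
    """Write a cohort as delimited text with canonical arm labels.

    Raises if the cohort has error-grade validation violations; warnings
    (such as a zero baseline) do not block writing. Missing assessments
    are written as empty cells; round-tripping through
    :func:`read_cohort` reproduces every score exactly.
    """
    report = validate_cohort(cohort)
    errors = [v for v in report.violations if v.severity == "error"]
    if errors:
        raise ValueError(
            f"refusing to write invalid cohort ({len(errors)} violations); "
            f"first: {errors[0]}"
        )
    df = cohort.to_dataframe()
    # pandas would write integer columns holding None as floats ("26.0")
    for col in COLUMNS[2:]:
        df[col] = df[col].map(lambda v: "" if v is None or pd.isna(v) else str(int(v)))
    df.to_csv(path, sep=delimiter, index=False)


@dataclass(frozen=True)
class Violation:
    """A single validation failure for one record."""

    record_id: str
    rule: str
    message: str
    severity: str = "error"  # "error" | "warning"


@dataclass
class ValidationReport:
    """All violations found in a cohort; passes iff the list is empty."""

    violations: list[Violation] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.violations

    @property
    def errors(self) -> list[Violation]:
        return [v for v in self.violations if v.severity == "error"]

    @property
    def warnings(self) -> list[Violation]:
        return [v for v in self.violations if v.severity == "warning"]

    def rules(self) -> set[str]:
        return {v.rule for v in self.violations}

    def to_json(self) -> str:
        return json.dumps(
            {
                "passed": self.passed,
                "violations": [
                    {
                        "record_id": v.record_id,
                        "rule": v.rule,
                        "message": v.message,
                        "severity": v.severity,
                    }
                    for v in self.violations
                ],
            },
            indent=2,
        )


def _check_scores(pid: str, tp: str, s: CapsScores, out: list[Violation]) -> None:
    if not (0 <= s.total <= TOTAL_MAX):
        out.append(Violation(pid, "total-range",
                             f"{tp}: total {s.total} outside [0, {TOTAL_MAX}]"))
    for name, value in zip("BCDE", (s.b, s.c, s.d, s.e)):
        hi = CLUSTER_MAX[name]
        if not (0 <= value <= hi):
            out.append(Violation(pid, f"cluster-{name}-range",
                                 f"{tp}: cluster {name} score {value} outside [0, {hi}]"))
    if s.cluster_sum() != s.total:
        out.append(Violation(pid, "cluster-sum",
                             f"{tp}: clusters sum to {s.cluster_sum()} != total {s.total}"))


def validate_cohort(cohort: Cohort) -> ValidationReport:
    """Check every record against every invariant; never raises on content.

    Rules: ``total-range``, ``cluster-{B,C,D,E}-range``, ``cluster-sum``
    (per timepoint), ``pre-zero`` (warning — the record cannot enter
    ratio-based analyses) and ``duplicate-id`` at cohort level. The report
    enumerates all violations, not just the first.
    """
    out: list[Violation] = []
    seen: set[str] = set()
    for rec in cohort.records:
        if rec.participant_id in seen:
            out.append(Violation(rec.participant_id, "duplicate-id",
                                 "participant_id occurs more than once"))
        seen.add(rec.participant_id)
        for tp in TIMEPOINTS:
            s = rec.scores(tp)
            if s is not None:
                _check_scores(rec.participant_id, tp, s, out)
        if rec.pre.total == 0:
            out.append(Violation(rec.participant_id, "pre-zero",
                                 "baseline total is 0; post/pre ratios undefined",
                                 severity="warning"))
    return ValidationReport(violations=out)
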