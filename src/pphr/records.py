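"""Consultation-record corpora: reading, validation, partitioning, summaries.

The atomic unit is a :class:`ConsultationRecord` — one patient question sent
to one physician on a web-based consultation platform, together with whether
and how fast the physician replied.  Corpora arrive as CSV (with header) or
JSONL, UTF-8.  Response times in source files may be bare minutes or
human-readable durations such as ``"8 h 12 min"``; internally everything is
minutes.
"""

from __future__ import annotations

import dataclasses
import json
import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConsultationRecord",
    "CorpusSplit",
    "CorpusValidationError",
    "SchemaError",
    "parse_duration_min",
    "format_duration_min",
    "read_records",
    "write_records",
    "split_corpus",
    "summarize_corpus",
]

REQUIRED_COLUMNS = (
    "question_id",
    "patient_code",
    "physician_code",
    "question_text",
    "response_status",
)

OPTIONAL_COLUMNS = (
    "department",
    "response_time",
    "created_hour",
    "patient_sex",
    "patient_age",
    "physician_title",
)


class SchemaError(ValueError):
    """A required column is missing or the file cannot be interpreted."""


class CorpusValidationError(ValueError):
    """One or more rows violate record invariants; carries row diagnostics."""

    def __init__(self, diagnostics: list[str]):
        self.diagnostics = list(diagnostics)
        super().__init__(
            "corpus validation failed:\n" + "\n".join(self.diagnostics)
        )


@dataclass(frozen=True)
class ConsultationRecord:
    """One web-based consultation request.

    ``response_time_min`` is present only when ``response_status`` is true:
    an unanswered request carries no response time.
    """

    question_id: str
    patient_code: str
    physician_code: str
    question_text: str
    response_status: bool
    department: str | None = None
    response_time_min: float | None = None
    created_hour: int | None = None
    patient_sex: str | None = None
    patient_age: float | None = None
    physician_title: str | None = None

    def __post_init__(self) -> None:
        if not self.question_id:
            raise ValueError("question_id must be non-empty")
        if not self.question_text or not self.question_text.strip():
            raise ValueError(
                f"record {self.question_id!r}: empty question_text"
            )
        if self.response_time_min is not None:
            if not self.response_status:
                raise ValueError(
                    f"record {self.question_id!r}: response_time present "
                    "but response_status is false"
                )
            if self.response_time_min < 0:
                raise ValueError(
                    f"record {self.question_id!r}: negative response_time"
                )


@dataclass(frozen=True)
class CorpusSplit:
    """Disjoint partition of a corpus into training and two test sets.

    ``test1`` records each carry, in ``test1_truth``, the code of the
    physician who tagged the question as within their expertise.
    """

    training: tuple[ConsultationRecord, ...]
    test1: tuple[ConsultationRecord, ...]
    test2: tuple[ConsultationRecord, ...]
    test1_truth: dict[str, str]


_DURATION_RE = re.compile(
    r"^\s*(?:(?P<h>\d+(?:\.\d+)?)\s*h(?:ours?)?)?"
    r"\s*(?:(?P<m>\d+(?:\.\d+)?)\s*min(?:utes?)?)?\s*$",
    re.IGNORECASE,
)

_NULLS = {"", "null", "none", "na", "nan"}


def parse_duration_min(value) -> float | None:
    """Parse a response time into minutes.

    Accepts bare numerics (minutes), ``"20 min"``, ``"8 h 12 min"``, ``"2 h"``
    and null-ish strings (empty, ``null``, ``NA``) which map to ``None``.
    """
    if value is None:
        return None
    if isinstance(value, (int, float)):
        return None if np.isnan(value) else float(value)
    s = str(value).strip()
    if s.lower() in _NULLS:
        return None
    try:
        return float(s)
    except ValueError:
        pass
    m = _DURATION_RE.match(s)
    if m is None or (m.group("h") is None and m.group("m") is None):
        raise ValueError(f"unparsable response_time: {value!r}")
    hours = float(m.group("h") or 0.0)
    minutes = float(m.group("m") or 0.0)
    return 60.0 * hours + minutes


def format_duration_min(minutes: float | None) -> str:
    """Render minutes as ``"Hh Mmin"`` (the source-file convention)."""
    if minutes is None:
        return "null"
    h, m = divmod(round(minutes), 60)
    if h and m:
        return f"{h} h {m} min"
    if h:
        return f"{h} h"
    return f"{m} min"


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in {"true", "1", "t", "yes"}:
        return True
    if s in {"false", "0", "f", "no"}:
        return False
    raise ValueError(f"unparsable response_status: {value!r}")


def _record_from_row(row: dict, idx: int) -> ConsultationRecord:
    def opt(key):
        v = row.get(key)
        if v is None:
            return None
        s = str(v).strip()
        return None if s.lower() in _NULLS else s

    try:
        status = _parse_bool(row["response_status"])
        rt = parse_duration_min(row.get("response_time"))
        age = opt("patient_age")
        hour = opt("created_hour")
        return ConsultationRecord(
            question_id=str(row["question_id"]).strip(),
            patient_code=str(row["patient_code"]).strip(),
            physician_code=str(row["physician_code"]).strip(),
            question_text=str(row["question_text"]),
            response_status=status,
            department=opt("department"),
            response_time_min=rt,
            created_hour=int(float(hour)) if hour is not None else None,
            patient_sex=opt("patient_sex"),
            patient_age=float(age) if age is not None else None,
            physician_title=opt("physician_title"),
        )
    except ValueError as exc:
        raise ValueError(f"row {idx}: {exc}") from exc


def read_records(
    path: str | Path,
    fmt: str | None = None,
    *,
    column_map: dict[str, str] | None = None,
    strict: bool = True,
) -> list[ConsultationRecord]:
    """Read a corpus from CSV or JSONL, preserving file order.

    Parameters
    ----------
    path:
        Input file.  Format inferred from the suffix unless ``fmt`` given.
    fmt:
        ``"csv"`` or ``"jsonl"``.
    column_map:
        Optional mapping from source column names to the canonical names
        (``question_id``, ``patient_code``, ...).
    strict:
        If true (default) any invariant-violating row raises
        :class:`CorpusValidationError` with row-level diagnostics; if false
        such rows are dropped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "jsonl" if path.suffix.lower() in {".jsonl", ".ndjson"} else "csv"
    if fmt == "csv":
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        rows = frame.to_dict(orient="records")
    elif fmt == "jsonl":
        rows = []
        with path.open(encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line:
                    rows.append(json.loads(line))
    else:
        raise ValueError(f"unknown format: {fmt!r}")

    if column_map:
        rows = [
            {column_map.get(k, k): v for k, v in row.items()} for row in rows
        ]

    if rows:
        missing = [c for c in REQUIRED_COLUMNS if c not in rows[0]]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    records: list[ConsultationRecord] = []
    diagnostics: list[str] = []
    seen: set[str] = set()
    for idx, row in enumerate(rows):
        try:
            rec = _record_from_row(row, idx)
            if rec.question_id in seen:
                raise ValueError(
                    f"row {idx}: duplicate question_id {rec.question_id!r}"
                )
            seen.add(rec.question_id)
            records.append(rec)
        except ValueError as exc:
            diagnostics.append(str(exc))
    if diagnostics:
        if strict:
            raise CorpusValidationError(diagnostics)
        warnings.warn(
            f"dropped {len(diagnostics)} invalid row(s); first: {diagnostics[0]}",
            stacklevel=2,
        )
    return records


def write_records(
    records: list[ConsultationRecord], path: str | Path, fmt: str | None = None
) -> None:
    """Write records as CSV or JSONL (round-trips with :func:`read_records`)."""
    path = Path(path)
    if fmt is None:
        fmt = "jsonl" if path.suffix.lower() in {".jsonl", ".ndjson"} else "csv"
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        d["response_time"] = (
            "" if r.response_time_min is None else r.response_time_min
        )
        del d["response_time_min"]
        rows.append(d)
    if fmt == "csv":
        pd.DataFrame(rows).to_csv(path, index=False)
    elif fmt == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for row in rows:
                fh.write(json.dumps(row, ensure_ascii=False) + "\n")
    else:
        raise ValueError(f"unknown format: {fmt!r}")


def split_corpus(
    records: list[ConsultationRecord],
    test1_labels: dict[str, str],
    test2_size: int,
    seed: int = 2023,
) -> CorpusSplit:
    """Partition a corpus into training / test1 / test2.

    ``test1`` comprises the records whose question_id appears in
    ``test1_labels`` (mapping question_id to the physician who vetted the
    question as within their expertise).  ``test2`` is sampled uniformly
    without replacement from the remainder; training is what is left.
    Deterministic for a fixed ``seed``.
    """
    by_id = {r.question_id: r for r in records}
    unknown = set(test1_labels) - set(by_id)
    if unknown:
        raise ValueError(
            f"test1 label(s) reference unknown question_id(s): {sorted(unknown)[:5]}"
        )
    test1 = tuple(r for r in records if r.question_id in test1_labels)
    remainder = [r for r in records if r.question_id not in test1_labels]
    if test2_size > len(remainder):
        raise ValueError(
            f"test2_size {test2_size} exceeds remaining corpus size {len(remainder)}"
        )
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(remainder), size=test2_size, replace=False)
    picked_set = set(int(i) for i in picked)
    test2 = tuple(remainder[i] for i in sorted(picked_set))
    training = tuple(
        r for i, r in enumerate(remainder) if i not in picked_set
    )
    return CorpusSplit(
        training=training,
        test1=test1,
        test2=test2,
        test1_truth=dict(test1_labels),
    )


_AGE_BINS = [(-np.inf, 20, "<20"), (20, 40, "20-39"), (40, 60, "40-59"), (60, np.inf, ">60")]
_HOUR_BINS = [(0, 6, "0-5"), (6, 12, "6-11"), (12, 18, "12-17"), (18, 24, "18-23")]


def summarize_corpus(records: list[ConsultationRecord]) -> pd.DataFrame:
    """Record-level summary: counts and percentages per categorical field.

    Returns a tidy frame with columns ``field``, ``category``, ``count``,
    ``percentage`` (2 decimals).  Percentages within one field sum to ~100
    over the records where the field is present.
    """
    if not records:
        raise ValueError("cannot summarize an empty corpus")

    def binned(value, bins):
        for lo, hi, label in bins:
            if lo <= value < hi:
                return label
        return None

    fields: dict[str, list[str]] = {}

    def add(field, value):
        if value is not None:
            fields.setdefault(field, []).append(str(value))

    for r in records:
        add("response_status", "True" if r.response_status else "False")
        add("patient_sex", r.patient_sex)
        add("physician_title", r.physician_title)
        add("department", r.department)
        if r.patient_age is not None:
            add("age_group", binned(r.patient_age, _AGE_BINS))
        if r.created_hour is not None:
            add("created_hour_group", binned(r.created_hour, _HOUR_BINS))

    rows = []
    for field, values in fields.items():
        counts = pd.Series(values).value_counts()
        total = int(counts.sum())
        for category, count in counts.items():
            rows.append(
                {
                    "field": field,
                    "category": category,
                    "count": int(count),
                    "percentage": round(100.0 * count / total, 2),
                }
            )
    return pd.DataFrame(rows, columns=["field", "category", "count", "percentage"])
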