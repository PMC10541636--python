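"""Query-log data model and TSV readers/writers.

One :class:`QueryLogRecord` is the atomic log unit: a single submitted
query together with the expansion on/off flag and the ranked list of
retrieved document ids (at most the top 30 are kept, mirroring the logging
of the original study system). :class:`ScenarioMeta` carries the
per-scenario constants — estimated difficulty and the perceived-performance
survey score — that the convergence analysis correlates against.

Files are tab-separated with a header row; a query may legitimately contain
commas, so the record delimiter must not be one. The ranked document ids
live in a single column as a comma-separated list. Timestamps are opaque
``HH:MM:SS`` strings: they are time-of-day only and can wrap across a
session, so ``seq`` is the authoritative within-session order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from qconv.errors import IntegrityError, SchemaError

DIFFICULTY_LEVELS = ("low", "medium", "high")

LOG_COLUMNS = (
    "log_id",
    "user_id",
    "scenario_id",
    "seq",
    "query_text",
    "sbqr",
    "timestamp",
    "doc_ids",
)

_TRUE_FLAGS = {"on", "true", "1", "yes"}
_FALSE_FLAGS = {"off", "false", "0", "no"}


@dataclass(frozen=True)
class LogDialect:
    """Delimiter configuration for query-log files.

    ``column_map`` renames file columns onto the canonical schema, so a
    third-party export with different headers can be ingested without
    rewriting the file.
    """

    delimiter: str = "\t"
    list_delimiter: str = ","
    column_map: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class QueryLogRecord:
    """One submitted query with its flag and ranked retrieval results."""

    log_id: str
    user_id: str
    scenario_id: int
    seq: int
    query_text: str
    sbqr_on: bool
    timestamp: str
    retrieved_doc_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.seq < 1:
            raise ValueError(f"seq must be positive, got {self.seq}")
        if not self.query_text.strip():
            raise ValueError(f"empty query_text in log record {self.log_id!r}")
        if len(self.retrieved_doc_ids) > 30:
            raise ValueError(
                f"record {self.log_id!r} keeps {len(self.retrieved_doc_ids)} "
                "retrieved documents; at most the top 30 are logged"
            )
        if len(set(self.retrieved_doc_ids)) != len(self.retrieved_doc_ids):
            raise IntegrityError(
                f"duplicate retrieved document ids in record {self.log_id!r}"
            )


@dataclass(frozen=True)
class ScenarioMeta:
    """Per-scenario study constants: difficulty and perceived performance."""

    scenario_id: int
    difficulty: str
    perceived_performance: float
    description: str = ""

    def __post_init__(self) -> None:
        if self.difficulty not in DIFFICULTY_LEVELS:
            raise ValueError(
                f"difficulty must be one of {DIFFICULTY_LEVELS}, "
                f"got {self.difficulty!r} for scenario {self.scenario_id}"
            )


def _parse_flag(raw: object, line_no: int) -> bool:
    text = str(raw).strip().lower()
    if text in _TRUE_FLAGS:
        return True
    if text in _FALSE_FLAGS:
        return False
    raise ValueError(f"unparseable SBQR flag {raw!r} on line {line_no}")


def sort_records(records: Iterable[QueryLogRecord]) -> list[QueryLogRecord]:
    """Canonical deterministic ordering: (user_id, scenario_id, seq)."""
    return sorted(records, key=lambda r: (r.user_id, r.scenario_id, r.seq))


def validate_records(records: Sequence[QueryLogRecord]) -> None:
    """Check cross-record invariants: seq unique within (user, scenario)."""
    seen: set[tuple[str, int, int]] = set()
    for rec in records:
        key = (rec.user_id, rec.scenario_id, rec.seq)
        if key in seen:
            raise IntegrityError(
                f"duplicate (user, scenario, seq) triple {key} in query log"
            )
        seen.add(key)


def read_query_log(path: str | Path, dialect: LogDialect | None = None) -> list[QueryLogRecord]:
    """Read a query-log TSV into validated, canonically sorted records.

    Raises :class:`SchemaError` on a missing column, :class:`IntegrityError`
    on duplicate (user, scenario, seq), and ``ValueError`` (with line
    number) on an unparseable SBQR flag.
    """
    dialect = dialect or LogDialect()
    frame = pd.read_csv(path, sep=dialect.delimiter, dtype=str, keep_default_na=False)
    if dialect.column_map:
        frame = frame.rename(columns=dialect.column_map)
    missing = [c for c in LOG_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"query log {path} is missing column(s): {', '.join(missing)}")

    records: list[QueryLogRecord] = []
    for idx, row in enumerate(frame.itertuples(index=False)):
        line_no = idx + 2  # header is line 1
        doc_field = getattr(row, "doc_ids").strip()
        doc_ids = tuple(
            d.strip() for d in doc_field.split(dialect.list_delimiter) if d.strip()
        ) if doc_field else ()
        records.append(
            QueryLogRecord(
                log_id=getattr(row, "log_id"),
                user_id=getattr(row, "user_id"),
                scenario_id=int(getattr(row, "scenario_id")),
                seq=int(getattr(row, "seq")),
                query_text=getattr(row, "query_text"),
                sbqr_on=_parse_flag(getattr(row, "sbqr"), line_no),
                timestamp=getattr(row, "timestamp"),
                retrieved_doc_ids=doc_ids,
            )
        )
    validate_records(records)
    return sort_records(records)


def write_query_log(
    records: Sequence[QueryLogRecord],
    path: str | Path,
    dialect: LogDialect | None = None,
) -> Path:
    """Serialize records to TSV such that ``read_query_log`` round-trips."""
    dialect = dialect or LogDialect()
    rows = [
        {
            "log_id": r.log_id,
            "user_id": r.user_id,
            "scenario_id": r.scenario_id,
            "seq": r.seq,
            "query_text": r.query_text,
            "sbqr": "On" if r.sbqr_on else "Off",
            "timestamp": r.timestamp,
            "doc_ids": dialect.list_delimiter.join(r.retrieved_doc_ids),
        }
        for r in records
    ]
    frame = pd.DataFrame(rows, columns=list(LOG_COLUMNS))
    path = Path(path)
    frame.to_csv(path, sep=dialect.delimiter, index=False)
    return path


def read_scenario_meta(path: str | Path) -> list[ScenarioMeta]:
    """Read the per-scenario difficulty / perceived-performance table."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ("scenario_id", "difficulty", "perceived_performance")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"scenario meta {path} is missing column(s): {', '.join(missing)}"
        )
    metas: list[ScenarioMeta] = []
    seen: set[int] = set()
    for row in frame.itertuples(index=False):
        sid = int(getattr(row, "scenario_id"))
        if sid in seen:
            raise IntegrityError(f"duplicate scenario_id {sid} in scenario meta")
        seen.add(sid)
        metas.append(
            ScenarioMeta(
                scenario_id=sid,
                difficulty=getattr(row, "difficulty").strip().lower(),
                perceived_performance=float(getattr(row, "perceived_performance")),
                description=getattr(row, "description", ""),
            )
        )
    return sorted(metas, key=lambda m: m.scenario_id)


def write_scenario_meta(metas: Sequence[ScenarioMeta], path: str | Path) -> Path:
    frame = pd.DataFrame(
        [
            {
                "scenario_id": m.scenario_id,
                "difficulty": m.difficulty,
                "perceived_performance": m.perceived_performance,
                "description": m.description,
            }
            for m in metas
        ]
    )
    path = Path(path)
    frame.to_csv(path, sep="\t", index=False)
    return path


def truncate_results(record: QueryLogRecord, k: int) -> QueryLogRecord:
    """Copy of ``record`` keeping only the ``k`` best-ranked documents."""
    if k < 0:
        raise ValueError("k must be non-negative")
    return replace(record, retrieved_doc_ids=record.retrieved_doc_ids[:k])
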