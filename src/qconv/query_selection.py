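"""Selection of the analysis query pair and per-scenario activity summaries.

Within each (user, scenario) session the analysis compares exactly two
queries: the first one submitted with the semantic recommender off (Q_A1)
and the last one submitted with it on (Q_Bn). Users were free to toggle
the recommender, so Q_Bn is the on-flagged record with maximal ``seq``
over the whole session — even when an off-flagged query follows it.
Sessions lacking either condition are excluded, not imputed, and the
exclusions are returned as data.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from qconv.logmodel import QueryLogRecord, sort_records

logger = logging.getLogger(__name__)

TokenizerFn = Callable[[str], frozenset[str]]


@dataclass(frozen=True)
class QueryPair:
    """Per (user, scenario): the Q_A1 / Q_Bn records and their result lists."""

    user_id: str
    scenario_id: int
    q_first_off: QueryLogRecord
    q_last_on: QueryLogRecord

    @property
    def r_first_off(self) -> tuple[str, ...]:
        """R_A1 — ranked documents retrieved for the first off-query."""
        return self.q_first_off.retrieved_doc_ids

    @property
    def r_last_on(self) -> tuple[str, ...]:
        """R_Bn — ranked documents retrieved for the last on-query."""
        return self.q_last_on.retrieved_doc_ids


@dataclass(frozen=True)
class ExcludedGroup:
    """A (user, scenario) session dropped from pair-based analyses."""

    user_id: str
    scenario_id: int
    reason: str


@dataclass(frozen=True)
class ActivitySummary:
    """Per-scenario query-activity aggregates."""

    scenario_id: int
    n_users: int
    avg_queries_per_user: float
    pct_queries_sbqr_on: float
    avg_terms_per_query: float
    avg_chars_per_query: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_queries_sbqr_on <= 100.0:
            raise ValueError("pct_queries_sbqr_on must be in [0, 100]")
        for name in ("avg_queries_per_user", "avg_terms_per_query", "avg_chars_per_query"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _group_records(
    records: Iterable[QueryLogRecord],
) -> dict[tuple[str, int], list[QueryLogRecord]]:
    groups: dict[tuple[str, int], list[QueryLogRecord]] = defaultdict(list)
    for rec in sort_records(records):
        groups[(rec.user_id, rec.scenario_id)].append(rec)
    return groups


def select_query_pairs(
    records: Sequence[QueryLogRecord],
) -> tuple[list[QueryPair], list[ExcludedGroup]]:
    """Pick Q_A1 / Q_Bn per (user, scenario) group.

    Returns the pairs plus the list of groups excluded because one of the
    two conditions never occurred; pairs + exclusions partition the groups.
    Order-insensitive: input records are canonically re-sorted first.
    """
    pairs: list[QueryPair] = []
    excluded: list[ExcludedGroup] = []
    for (user_id, scenario_id), group in _group_records(records).items():
        offs = [r for r in group if not r.sbqr_on]
        ons = [r for r in group if r.sbqr_on]
        if not offs or not ons:
            reason = "no sbqr-off query" if not offs else "no sbqr-on query"
            excluded.append(ExcludedGroup(user_id, scenario_id, reason))
            continue
        pairs.append(
            QueryPair(
                user_id=user_id,
                scenario_id=scenario_id,
                q_first_off=min(offs, key=lambda r: r.seq),
                q_last_on=max(ons, key=lambda r: r.seq),
            )
        )
    pairs.sort(key=lambda p: (p.scenario_id, p.user_id))
    excluded.sort(key=lambda e: (e.scenario_id, e.user_id))
    return pairs, excluded


def summarize_activity(
    records: Sequence[QueryLogRecord],
    tokenizer: TokenizerFn | None = None,
    per_user: bool = True,
) -> list[ActivitySummary]:
    """Per-scenario activity summary.

    ``pct_queries_sbqr_on`` defaults to the mean over users of each user's
    within-user percentage of on-flagged queries (users weighted equally);
    ``per_user=False`` pools all of a scenario's queries instead. The same
    tokenizer used by the similarity stage should be passed so terms-per-
    query is counted on one vocabulary model; by default the package
    tokenizer is used.
    """
    if tokenizer is None:
        from qconv.similarity_analysis import tokenize_query

        tokenizer = tokenize_query

    by_scenario: dict[int, dict[str, list[QueryLogRecord]]] = defaultdict(
        lambda: defaultdict(list)
    )
    for rec in records:
        by_scenario[rec.scenario_id][rec.user_id].append(rec)

    summaries: list[ActivitySummary] = []
    for scenario_id in sorted(by_scenario):
        users = by_scenario[scenario_id]
        all_recs = [r for recs in users.values() for r in recs]
        if not all_recs:
            logger.warning("scenario %s has no records; omitted", scenario_id)
            continue
        counts = [len(recs) for recs in users.values()]
        if per_user:
            pct = 100.0 * sum(
                sum(r.sbqr_on for r in recs) / len(recs) for recs in users.values()
            ) / len(users)
        else:
            pct = 100.0 * sum(r.sbqr_on for r in all_recs) / len(all_recs)
        n_terms = [len(tokenizer(r.query_text)) for r in all_recs]
        n_chars = [len(r.query_text) for r in all_recs]
        summaries.append(
            ActivitySummary(
                scenario_id=scenario_id,
                n_users=len(users),
                avg_queries_per_user=sum(counts) / len(counts),
                pct_queries_sbqr_on=pct,
                avg_terms_per_query=sum(n_terms) / len(n_terms),
                avg_chars_per_query=sum(n_chars) / len(n_chars),
            )
        )
    return summaries
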