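"""Lexical similarity between the first off-query and the last on-query.

Each query is reduced to a term vector: its text is lower-cased, split on
whitespace and punctuation (intra-token hyphens kept by default), and the
tokens merged into a set, so "dcis, breast cancer" and "non-invasive dcis
breast cancer" compare term-wise. The similarity of the pair is the
Jaccard coefficient of the two sets,

    J(V_A1, V_Bn) = |V_A1 ∩ V_Bn| / |V_A1 ∪ V_Bn|,

aggregated per scenario as mean, sample (n−1) SD, and median. The overall
study-level similarity is the unweighted mean of the scenario means; a
pair-weighted pooled mean is available as an option.
"""

from __future__ import annotations

import logging
import re
import statistics
from collections import defaultdict
from dataclasses import dataclass
from typing import Callable, Sequence

from qconv.errors import EmptyTermSetError
from qconv.query_selection import QueryPair

logger = logging.getLogger(__name__)

# a term is a run of word characters, optionally hyphen-joined
_TOKEN_HYPHEN = re.compile(r"\w+(?:-\w+)*")
_TOKEN_PLAIN = re.compile(r"\w+")


def tokenize_query(query_text: str, keep_hyphens: bool = True) -> frozenset[str]:
    """Lower-case and split a query into its merged term set.

    ``keep_hyphens=True`` treats "non-invasive" as one term; ``False``
    splits it into two. Raises :class:`EmptyTermSetError` if no token
    survives (e.g. the text is all punctuation).
    """
    pattern = _TOKEN_HYPHEN if keep_hyphens else _TOKEN_PLAIN
    terms = frozenset(pattern.findall(query_text.lower()))
    if not terms:
        raise EmptyTermSetError(f"query {query_text!r} yields no terms")
    return terms


def jaccard(a: frozenset[str] | set[str], b: frozenset[str] | set[str]) -> float:
    """|a ∩ b| / |a ∪ b|; undefined (raises) when both sets are empty."""
    if not a and not b:
        raise EmptyTermSetError("Jaccard is undefined for two empty sets")
    return len(set(a) & set(b)) / len(set(a) | set(b))


@dataclass(frozen=True)
class SimilaritySummary:
    """Per-scenario aggregate of the pairwise Jaccard scores."""

    scenario_id: int
    mean_jaccard: float
    sd_jaccard: float
    median_jaccard: float
    n_pairs: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_jaccard <= 1.0:
            raise ValueError("mean_jaccard must lie in [0, 1]")
        if not 0.0 <= self.median_jaccard <= 1.0:
            raise ValueError("median_jaccard must lie in [0, 1]")
        if self.sd_jaccard < 0:
            raise ValueError("sd_jaccard must be non-negative")


def pair_jaccard(
    pair: QueryPair,
    tokenizer: Callable[[str], frozenset[str]] = tokenize_query,
) -> float:
    """Jaccard similarity of one Q_A1 / Q_Bn pair's term sets."""
    return jaccard(tokenizer(pair.q_first_off.query_text), tokenizer(pair.q_last_on.query_text))


def scenario_similarity(
    pairs: Sequence[QueryPair],
    tokenizer: Callable[[str], frozenset[str]] = tokenize_query,
) -> tuple[list[SimilaritySummary], dict[int, list[float]]]:
    """Aggregate pairwise Jaccard scores per scenario.

    Returns the summaries plus the raw per-pair scores keyed by scenario,
    which downstream statistics (and tests) consume directly.
    """
    scores: dict[int, list[float]] = defaultdict(list)
    for pair in pairs:
        scores[pair.scenario_id].append(pair_jaccard(pair, tokenizer))

    summaries: list[SimilaritySummary] = []
    for scenario_id in sorted(scores):
        vals = scores[scenario_id]
        if not vals:
            logger.warning("scenario %s has no pairs; omitted", scenario_id)
            continue
        summaries.append(
            SimilaritySummary(
                scenario_id=scenario_id,
                mean_jaccard=statistics.fmean(vals),
                sd_jaccard=statistics.stdev(vals) if len(vals) > 1 else 0.0,
                median_jaccard=statistics.median(vals),
                n_pairs=len(vals),
            )
        )
    return summaries, dict(scores)


def overall_similarity(
    summaries: Sequence[SimilaritySummary], weighted: bool = False
) -> float:
    """Study-level Jaccard: unweighted mean of scenario means by default.

    ``weighted=True`` pools instead, weighting each scenario mean by its
    number of pairs.
    """
    if not summaries:
        raise ValueError("overall_similarity needs at least one scenario summary")
    if weighted:
        total = sum(s.n_pairs for s in summaries)
        return sum(s.mean_jaccard * s.n_pairs for s in summaries) / total
    return statistics.fmean(s.mean_jaccard for s in summaries)
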