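"""Result-set convergence via Shannon entropy.

For each scenario and condition (recommender off vs on), the result set is
the union over participants of their top-k retrieved documents (k = 10 by
default). A document's frequency is the number of participants whose top-k
list contains it — once per participant, not once per rank position — and
its probability score x is that frequency divided by the total frequency
mass. The condition's entropy is

    H = − Σ_d  x_d · log(x_d)

in a configurable base (2 by default). Convergence is a *drop* in entropy
when the recommender is on; the headline quantity is the percent
difference 100·(H_on − H_off)/H_off, which is invariant to the log base,
and its Pearson correlation with the per-scenario perceived-performance
survey score.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

from scipy import stats

from qconv.errors import DegenerateInputError, QconvError
from qconv.logmodel import ScenarioMeta
from qconv.query_selection import QueryPair

logger = logging.getLogger(__name__)

Condition = Literal["sbqr_off", "sbqr_on"]


@dataclass(frozen=True)
class ResultDistribution:
    """Document-frequency distribution of one scenario × condition."""

    scenario_id: int
    condition: Condition
    k: int
    doc_freq: Mapping[str, int]
    n_participants: int

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.doc_freq.values()):
            raise ValueError("all document frequencies must be >= 1")
        total = sum(self.doc_freq.values())
        if total > self.k * self.n_participants:
            raise ValueError(
                "total frequency exceeds k × participants; counting is broken"
            )

    @property
    def probs(self) -> dict[str, float]:
        """Probability score per document: frequency / total mass."""
        total = sum(self.doc_freq.values())
        return {d: c / total for d, c in self.doc_freq.items()}


def build_result_distributions(
    pairs: Sequence[QueryPair],
    condition: Condition,
    k: int = 10,
    dedupe_per_participant: bool = True,
) -> dict[int, ResultDistribution]:
    """Tally per-scenario document frequencies for one condition.

    Each participant's result list is truncated to its first ``k`` entries.
    With ``dedupe_per_participant`` (the default) a participant contributes
    at most one count per document; the pooled alternative counts every
    rank position. Participants with an empty list under this condition
    carry no frequency mass and are dropped with a warning; a scenario
    where *every* list is empty is an error.
    """
    if condition not in ("sbqr_off", "sbqr_on"):
        raise ValueError(f"unknown condition {condition!r}")
    if k < 1:
        raise ValueError("k must be >= 1")

    by_scenario: dict[int, list[tuple[str, ...]]] = {}
    for pair in pairs:
        docs = pair.r_first_off if condition == "sbqr_off" else pair.r_last_on
        by_scenario.setdefault(pair.scenario_id, []).append(docs[:k])

    out: dict[int, ResultDistribution] = {}
    for scenario_id in sorted(by_scenario):
        lists = by_scenario[scenario_id]
        contributing = [lst for lst in lists if lst]
        if not contributing:
            raise QconvError(
                f"scenario {scenario_id}: every {condition} result list is empty"
            )
        if len(contributing) < len(lists):
            logger.warning(
                "scenario %s: dropped %d participant(s) with empty %s lists",
                scenario_id,
                len(lists) - len(contributing),
                condition,
            )
        freq: Counter[str] = Counter()
        for lst in contributing:
            freq.update(set(lst) if dedupe_per_participant else lst)
        out[scenario_id] = ResultDistribution(
            scenario_id=scenario_id,
            condition=condition,
            k=k,
            doc_freq=dict(freq),
            n_participants=len(contributing),
        )
    return out


def shannon_entropy(dist: ResultDistribution | Mapping[str, float], log_base: float = 2.0) -> float:
    """−Σ x·log(x) over the distribution's probability scores."""
    probs = dist.probs if isinstance(dist, ResultDistribution) else dict(dist)
    if any(p <= 0 for p in probs.values()):
        raise ValueError("zero/negative probability; zero-count docs must be absent")
    total = sum(probs.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"probabilities sum to {total}, not 1")
    return -sum(p * math.log(p, log_base) for p in probs.values())


def entropy_difference_pct(entropy_off: float, entropy_on: float) -> float:
    """Percent change 100·(H_on − H_off)/H_off; negative means convergence."""
    if entropy_off <= 0:
        raise DegenerateInputError(
            "entropy difference is undefined when the off-condition entropy is 0"
        )
    return 100.0 * (entropy_on - entropy_off) / entropy_off


@dataclass(frozen=True)
class ConvergenceReport:
    """Per-scenario entropy pair, percent difference, and survey score."""

    scenario_id: int
    entropy_off: float
    entropy_on: float
    pct_diff: float
    perceived_performance: float

    def __post_init__(self) -> None:
        expected = entropy_difference_pct(self.entropy_off, self.entropy_on)
        if abs(self.pct_diff - expected) > 1e-6:
            raise ValueError(
                f"pct_diff {self.pct_diff} inconsistent with entropies "
                f"(expected {expected})"
            )


def convergence_reports(
    pairs: Sequence[QueryPair],
    meta: Sequence[ScenarioMeta],
    k: int = 10,
    log_base: float = 2.0,
    dedupe_per_participant: bool = True,
) -> list[ConvergenceReport]:
    """Full entropy stage: distributions → entropies → percent differences."""
    perf = {m.scenario_id: m.perceived_performance for m in meta}
    dist_off = build_result_distributions(pairs, "sbqr_off", k, dedupe_per_participant)
    dist_on = build_result_distributions(pairs, "sbqr_on", k, dedupe_per_participant)
    reports: list[ConvergenceReport] = []
    for scenario_id in sorted(dist_off):
        if scenario_id not in dist_on or scenario_id not in perf:
            logger.warning("scenario %s lacks on-condition or metadata; omitted", scenario_id)
            continue
        h_off = shannon_entropy(dist_off[scenario_id], log_base)
        h_on = shannon_entropy(dist_on[scenario_id], log_base)
        reports.append(
            ConvergenceReport(
                scenario_id=scenario_id,
                entropy_off=h_off,
                entropy_on=h_on,
                pct_diff=entropy_difference_pct(h_off, h_on),
                perceived_performance=perf[scenario_id],
            )
        )
    return reports


def correlate_convergence(reports: Sequence[ConvergenceReport]) -> float:
    """Sample Pearson correlation of pct_diff against perceived performance."""
    if len(reports) < 3:
        raise ValueError("Pearson correlation needs at least 3 scenarios")
    x = [r.pct_diff for r in reports]
    y = [r.perceived_performance for r in reports]
    if len(set(x)) == 1 or len(set(y)) == 1:
        raise DegenerateInputError("zero variance; correlation undefined")
    return float(stats.pearsonr(x, y).statistic)
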