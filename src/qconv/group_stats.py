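"""Group statistics on the per-scenario Jaccard scores.

The analysis plan mirrors standard practice for bounded similarity scores:
test each scenario's scores for normality (Kolmogorov-Smirnov against a
normal with the group's sample mean and SD — parameters are moment-matched,
no Lilliefors correction), test variance homogeneity across scenarios
(both Bartlett and Levene are reported), and, since Jaccard scores are
typically non-normal, compare group medians with the nonparametric
Kruskal-Wallis test. ``decide_median_test`` records the full decision
trail at a given alpha.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from scipy import stats

from qconv.errors import DegenerateInputError

logger = logging.getLogger(__name__)

ScoresByScenario = Mapping[int, Sequence[float]]


@dataclass(frozen=True)
class TestReport:
    test_name: str
    statistic: float
    p_value: float
    groups: tuple[int, ...]
    degenerate: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if not self.degenerate and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


def test_normality(scores_by_scenario: ScoresByScenario) -> list[TestReport]:
    """One KS-vs-moment-matched-normal report per scenario.

    Groups with fewer than 3 scores are skipped with a warning; a constant
    group is returned flagged degenerate (the reference normal has zero SD).
    """
    reports: list[TestReport] = []
    for scenario_id in sorted(scores_by_scenario):
        vals = list(scores_by_scenario[scenario_id])
        if len(vals) < 3:
            logger.warning("scenario %s has < 3 scores; normality test skipped", scenario_id)
            continue
        mu = statistics.fmean(vals)
        sd = statistics.stdev(vals)
        if sd == 0:
            reports.append(
                TestReport(
                    "kolmogorov_smirnov",
                    float("nan"),
                    float("nan"),
                    (scenario_id,),
                    degenerate=True,
                    note="constant scores; reference normal undefined",
                )
            )
            continue
        res = stats.kstest(vals, "norm", args=(mu, sd))
        reports.append(
            TestReport("kolmogorov_smirnov", float(res.statistic), float(res.pvalue), (scenario_id,))
        )
    return reports


def test_variance_homogeneity(scores_by_scenario: ScoresByScenario) -> list[TestReport]:
    """Bartlett and Levene reports over all scenarios with >= 2 scores."""
    usable = {
        sid: list(v) for sid, v in sorted(scores_by_scenario.items()) if len(v) >= 2
    }
    if len(usable) < 2:
        raise DegenerateInputError("variance homogeneity needs >= 2 groups of >= 2 scores")
    groups = tuple(usable)
    samples = list(usable.values())
    reports = []
    for name, func in (("bartlett", stats.bartlett), ("levene", stats.levene)):
        if all(statistics.pstdev(s) == 0 for s in samples):
            reports.append(
                TestReport(name, float("nan"), float("nan"), groups, degenerate=True,
                           note="all groups constant; variances undefined")
            )
            continue
        res = func(*samples)
        reports.append(TestReport(name, float(res.statistic), float(res.pvalue), groups))
    return reports


def test_median_difference(scores_by_scenario: ScoresByScenario) -> TestReport:
    """Single Kruskal-Wallis report across all scenarios."""
    usable = {sid: list(v) for sid, v in sorted(scores_by_scenario.items()) if v}
    if len(usable) < 2:
        raise DegenerateInputError("median-difference test needs >= 2 groups")
    groups = tuple(usable)
    samples = list(usable.values())
    pooled = [x for s in samples for x in s]
    if len(set(pooled)) == 1:
        return TestReport(
            "kruskal_wallis", 0.0, float("nan"), groups, degenerate=True,
            note="all scores identical across groups",
        )
    res = stats.kruskal(*samples)
    return TestReport("kruskal_wallis", float(res.statistic), float(res.pvalue), groups)


@dataclass(frozen=True)
class StatsDecision:
    """Decision trail of the staged analysis at a given alpha."""

    alpha: float
    normality: tuple[TestReport, ...]
    variance: tuple[TestReport, ...]
    median: TestReport | None
    any_non_normal: bool
    trail: tuple[str, ...] = field(default_factory=tuple)


def decide_median_test(
    scores_by_scenario: ScoresByScenario, alpha: float = 0.05
) -> StatsDecision:
    """Run the staged plan: normality → variance checks → Kruskal-Wallis.

    Kruskal-Wallis is run whenever any group fails normality at ``alpha``
    (the typical outcome for Jaccard scores, which pile up at 1.0); the
    trail records every step so a report can reproduce the reasoning.
    """
    trail: list[str] = []
    normality = test_normality(scores_by_scenario)
    rejected = [r.groups[0] for r in normality if not r.degenerate and r.p_value < alpha]
    any_non_normal = bool(rejected) or any(r.degenerate for r in normality)
    trail.append(
        f"KS normality at alpha={alpha}: non-normal scenarios {rejected or 'none'}"
    )
    variance = tuple(test_variance_homogeneity(scores_by_scenario))
    for rep in variance:
        trail.append(f"{rep.test_name}: statistic={rep.statistic:.4g} p={rep.p_value:.4g}")
    median = None
    if any_non_normal:
        median = test_median_difference(scores_by_scenario)
        trail.append(
            f"non-normal -> Kruskal-Wallis: statistic={median.statistic:.4g} "
            f"p={median.p_value:.4g}"
        )
    else:
        trail.append("all groups consistent with normality; Kruskal-Wallis not triggered")
    return StatsDecision(
        alpha=alpha,
        normality=tuple(normality),
        variance=variance,
        median=median,
        any_non_normal=any_non_normal,
        trail=tuple(trail),
    )
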