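"""Published per-scenario constants of the original user study.

These are *inputs* to the analysis, not outputs: the five scenarios'
estimated difficulty and mean perceived-performance survey scores, the
published per-scenario Jaccard summaries, and the published entropy pairs
for the two recommender conditions. They serve as the default scenario
metadata for synthetic runs and as the worked-example inputs for the
in-study arithmetic (percent entropy difference, its correlation with
perceived performance, and the overall similarity).
"""

from __future__ import annotations

from qconv.logmodel import ScenarioMeta

STUDY_SCENARIO_META: tuple[ScenarioMeta, ...] = (
    ScenarioMeta(1, "medium", 4.24, "concussion after a car accident"),
    ScenarioMeta(2, "low", 3.94, "noninvasive breast cancer (DCIS)"),
    ScenarioMeta(3, "medium", 4.42, "smokers diagnosed with PTSD"),
    ScenarioMeta(4, "high", 4.09, "herbal supplements for weight loss"),
    ScenarioMeta(5, "medium", 4.55, "mononucleosis with enlarged spleen"),
)

# published per-scenario Jaccard summaries: mean, SD, median
STUDY_JACCARD_SUMMARY: dict[int, tuple[float, float, float]] = {
    1: (0.69, 0.35, 0.8),
    2: (0.86, 0.22, 1.0),
    3: (0.80, 0.32, 1.0),
    4: (0.71, 0.37, 1.0),
    5: (0.79, 0.33, 1.0),
}

# published result-set entropies: (recommender off, recommender on)
STUDY_ENTROPY_PAIRS: dict[int, tuple[float, float]] = {
    1: (4.4384, 3.6747),
    2: (3.0688, 3.3858),
    3: (3.8411, 3.5537),
    4: (3.9398, 4.0709),
    5: (3.6617, 2.9248),
}

N_PARTICIPANTS = 33
TOP_K = 10
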