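"""End-to-end orchestration: logs → pairs → similarity → entropy → stats.

``run_pipeline`` executes the three analysis stages in order on either a
log file or a freshly simulated study, assembles the per-scenario tables
(activity, similarity, convergence), runs the group statistics on the
similarity scores, and — when asked — persists every intermediate as TSV
so each stage is independently auditable. Stage outputs are pure
functions of (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from qconv._version import __version__
from qconv.entropy_analysis import (
    ConvergenceReport,
    convergence_reports,
    correlate_convergence,
)
from qconv.errors import QconvError
from qconv.group_stats import StatsDecision, decide_median_test
from qconv.logmodel import (
    QueryLogRecord,
    ScenarioMeta,
    read_query_log,
    read_scenario_meta,
    write_query_log,
)
from qconv.query_selection import (
    ActivitySummary,
    ExcludedGroup,
    QueryPair,
    select_query_pairs,
    summarize_activity,
)
from qconv.similarity_analysis import (
    SimilaritySummary,
    overall_similarity,
    scenario_similarity,
    tokenize_query,
)
from qconv.study_tables import STUDY_SCENARIO_META
from qconv.synthetic_data import SimConfig, default_lexicon, generate_log

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one pipeline run."""

    mode: str = "simulate"  # "simulate" or "log_file"
    log_path: str | None = None
    meta_path: str | None = None
    out_dir: str | None = None
    k: int = 10
    alpha: float = 0.05
    log_base: float = 2.0
    keep_hyphens: bool = True
    per_user_pct: bool = True
    weighted_overall: bool = False
    dedupe_per_participant: bool = True
    seed: int = 0
    sim: SimConfig | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "log_file"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.mode == "log_file" and not self.log_path:
            raise ValueError("log_file mode requires log_path")


@dataclass(frozen=True)
class StudyReport:
    """All tables and statistics from one run, plus provenance."""

    activity: tuple[ActivitySummary, ...]
    similarity: tuple[SimilaritySummary, ...]
    convergence: tuple[ConvergenceReport, ...]
    pairs: tuple[QueryPair, ...]
    exclusions: tuple[ExcludedGroup, ...]
    scores_by_scenario: dict[int, list[float]]
    stats: StatsDecision | None
    overall_jaccard: float
    pearson_r: float | None
    n_records: int
    n_distinct_queries: int
    provenance: dict

    def activity_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(a) for a in self.activity])

    def similarity_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(s) for s in self.similarity])

    def convergence_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(c) for c in self.convergence])

    def summary_text(self) -> str:
        lines = [
            f"qconv {self.provenance['version']} study report",
            f"records: {self.n_records}   distinct queries: {self.n_distinct_queries}",
            f"pairs: {len(self.pairs)}   excluded groups: {len(self.exclusions)}",
            "",
            "Query activity by scenario:",
            self.activity_frame().to_string(index=False, float_format="%.2f"),
            "",
            "Query similarity (Jaccard of Q_A1 vs Q_Bn) by scenario:",
            self.similarity_frame().to_string(index=False, float_format="%.2f"),
            f"Overall Jaccard similarity: {self.overall_jaccard:.2f}",
            "",
            "Result-set entropy by scenario:",
            self.convergence_frame().to_string(index=False, float_format="%.4f"),
        ]
        if self.pearson_r is not None:
            lines.append(
                f"Pearson r (entropy difference % vs perceived performance): "
                f"{self.pearson_r:.2f}"
            )
        if self.stats is not None:
            lines += ["", "Statistical analysis:"] + [f"  {s}" for s in self.stats.trail]
        return "\n".join(lines)


def load_records(config: RunConfig) -> list[QueryLogRecord]:
    if config.mode == "log_file":
        return read_query_log(config.log_path)
    sim = config.sim or SimConfig(seed=config.seed, k=config.k)
    if sim.seed != config.seed:
        sim = dataclasses.replace(sim, seed=config.seed)
    return generate_log(sim, default_lexicon())


def load_meta(config: RunConfig) -> list[ScenarioMeta]:
    if config.meta_path:
        return read_scenario_meta(config.meta_path)
    return list(STUDY_SCENARIO_META)


def run_pipeline(config: RunConfig) -> StudyReport:
    """Execute every stage in order and assemble the report.

    Any stage failure aborts with a stage-named error; partially written
    outputs are removed.
    """
    out_dir = Path(config.out_dir) if config.out_dir else None
    written: list[Path] = []
    try:
        records = _stage("ingest", lambda: load_records(config))
        meta = _stage("metadata", lambda: load_meta(config))
        tokenizer = lambda q: tokenize_query(q, keep_hyphens=config.keep_hyphens)

        activity = _stage(
            "activity",
            lambda: summarize_activity(records, tokenizer, per_user=config.per_user_pct),
        )
        pairs, exclusions = _stage("pair-selection", lambda: select_query_pairs(records))
        summaries, scores = _stage(
            "similarity", lambda: scenario_similarity(pairs, tokenizer)
        )
        overall = overall_similarity(summaries, weighted=config.weighted_overall)
        # logs without retrieval results (queries only) support the
        # similarity stage but carry no frequency mass for the entropy stage
        has_results = any(p.r_first_off or p.r_last_on for p in pairs)
        if has_results:
            reports = _stage(
                "entropy",
                lambda: convergence_reports(
                    pairs,
                    meta,
                    k=config.k,
                    log_base=config.log_base,
                    dedupe_per_participant=config.dedupe_per_participant,
                ),
            )
        else:
            logger.warning("no retrieved documents in any pair; entropy stage skipped")
            reports = []
        pearson = correlate_convergence(reports) if len(reports) >= 3 else None
        stats = (
            _stage("group-stats", lambda: decide_median_test(scores, alpha=config.alpha))
            if len(scores) >= 2
            else None
        )

        report = StudyReport(
            activity=tuple(activity),
            similarity=tuple(summaries),
            convergence=tuple(reports),
            pairs=tuple(pairs),
            exclusions=tuple(exclusions),
            scores_by_scenario=scores,
            stats=stats,
            overall_jaccard=overall,
            pearson_r=pearson,
            n_records=len(records),
            n_distinct_queries=len({r.query_text for r in records}),
            provenance={
                "version": __version__,
                "config": {
                    k: v for k, v in dataclasses.asdict(config).items() if k != "sim"
                },
                "seed": config.seed,
            },
        )
        if out_dir is not None:
            written = _write_outputs(report, records, out_dir)
        return report
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise


def _stage(name: str, fn):
    try:
        return fn()
    except QconvError as exc:
        raise QconvError(f"stage {name!r} failed: {exc}") from exc


def _write_outputs(
    report: StudyReport, records: Sequence[QueryLogRecord], out_dir: Path
) -> list[Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    written.append(write_query_log(records, out_dir / "log.tsv"))
    pair_rows = [
        {
            "user_id": p.user_id,
            "scenario_id": p.scenario_id,
            "q_first_off": p.q_first_off.query_text,
            "q_last_on": p.q_last_on.query_text,
            "seq_off": p.q_first_off.seq,
            "seq_on": p.q_last_on.seq,
        }
        for p in report.pairs
    ]
    for name, frame in (
        ("pairs.tsv", pd.DataFrame(pair_rows)),
        ("exclusions.tsv", pd.DataFrame([dataclasses.asdict(e) for e in report.exclusions])),
        ("activity.tsv", report.activity_frame()),
        ("similarity.tsv", report.similarity_frame()),
        ("convergence.tsv", report.convergence_frame()),
    ):
        path = out_dir / name
        frame.to_csv(path, sep="\t", index=False)
        written.append(path)

    scores_path = out_dir / "jaccard_scores.tsv"
    pd.DataFrame(
        [
            {"scenario_id": sid, "jaccard": score}
            for sid, vals in sorted(report.scores_by_scenario.items())
            for score in vals
        ]
    ).to_csv(scores_path, sep="\t", index=False)
    written.append(scores_path)

    summary_path = out_dir / "summary.txt"
    summary_path.write_text(report.summary_text() + "\n")
    written.append(summary_path)

    prov_path = out_dir / "provenance.json"
    prov_path.write_text(json.dumps(report.provenance, indent=1, default=str))
    written.append(prov_path)
    return written
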