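"""Shared fixtures: the published worked-example session and small synthetic logs."""

from __future__ import annotations

import pytest

from qconv.logmodel import QueryLogRecord
from qconv.synthetic_data import SimConfig, default_lexicon, generate_log

# the published six-query example session (user 005, scenario 2): the user
# starts with "dcis" off, refines it, toggles the recommender, and ends
# with "dcis, breast cancer" as the last on-flagged query.
WORKED_EXAMPLE_ROWS = [
    ("1000006702", 1, "dcis", False, "09:54:34"),
    ("1000006712", 2, "non-invasive dcis", False, "09:55:11"),
    ("1000006717", 3, "non-invasive dcis breast cancer", False, "09:55:30"),
    ("1000006762", 4, "non-invasive dcis breast cancer", True, "09:57:39"),
    ("1000006776", 5, "dcis, breast cancer", True, "09:59:23"),
    ("1000006795", 6, "dcis, breast cancer", False, "10:00:30"),
]


@pytest.fixture()
def worked_example_records() -> list[QueryLogRecord]:
    return [
        QueryLogRecord(
            log_id=log_id,
            user_id="U005",
            scenario_id=2,
            seq=seq,
            query_text=query,
            sbqr_on=flag,
            timestamp=ts,
        )
        for log_id, seq, query, flag, ts in WORKED_EXAMPLE_ROWS
    ]


@pytest.fixture()
def worked_example_tsv(tmp_path):
    lines = ["log_id\tuser_id\tscenario_id\tseq\tquery_text\tsbqr\ttimestamp\tdoc_ids"]
    for log_id, seq, query, flag, ts in WORKED_EXAMPLE_ROWS:
        lines.append(
            f"{log_id}\tU005\t2\t{seq}\t{query}\t{'On' if flag else 'Off'}\t{ts}\t"
        )
    path = tmp_path / "worked_example.tsv"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture(scope="session")
def small_sim_config() -> SimConfig:
    """A reduced study (8 users) for tests that only need log structure."""
    return SimConfig(n_users=8, n_docs=120, doc_length=25, seed=7)


@pytest.fixture(scope="session")
def small_log(small_sim_config):
    return generate_log(small_sim_config, default_lexicon())


@pytest.fixture(scope="session")
def study_log():
    """A full-shape study log: 33 users × 5 scenarios, default conditions."""
    return generate_log(SimConfig(seed=11), default_lexicon())
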