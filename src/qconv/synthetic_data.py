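"""Synthetic query logs with the structure the convergence analysis assumes.

The generator is a desk-scale stand-in for a concept-mapping EHR search
stack: a toy lexicon maps each medical concept to a handful of synonym
terms; documents are term bags focused on one concept; retrieval is summed
TF×IDF over query terms; and the semantic recommender replaces every
recognized term with its concept's full synonym list before retrieval.

Simulated users are the mechanism of interest. Each user formulates a
query by picking, per target concept, either the canonical synonym or —
with the scenario's *synonym-divergence* probability — a random
alternative. High divergence makes different users retrieve different
documents when the recommender is off; turning it on collapses all
synonym choices onto the same expanded query, so the cross-user result
distribution converges (entropy drops). Two further knobs complete the
difficulty model: *query-noise* (chance of an off-target term in the
query, which an indiscriminate expander amplifies — the route by which
entropy can rise in easy scenarios) and *edit* probability (chance the
user changes the query between submissions, which lowers the Q_A1/Q_Bn
Jaccard similarity).

Everything is deterministic given a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import log
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from qconv.errors import IntegrityError, QconvError
from qconv.logmodel import QueryLogRecord, sort_records, validate_records

MAX_LOGGED_RESULTS = 30


# ---------------------------------------------------------------------------
# lexicon and corpus


@dataclass(frozen=True)
class ConceptLexicon:
    """Unambiguous concept → synonym-term mapping (term level only)."""

    concepts: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        owner: dict[str, str] = {}
        for cid, terms in self.concepts.items():
            if not terms:
                raise ValueError(f"concept {cid!r} has no synonym terms")
            for t in terms:
                if not t or t != t.lower() or any(ch.isspace() for ch in t):
                    raise ValueError(f"invalid synonym term {t!r} in concept {cid!r}")
                if t in owner:
                    raise IntegrityError(
                        f"term {t!r} belongs to both {owner[t]!r} and {cid!r}"
                    )
                owner[t] = cid
        object.__setattr__(self, "_owner", owner)

    def concept_of(self, term: str) -> str | None:
        return self._owner.get(term)

    def synonyms(self, concept_id: str) -> tuple[str, ...]:
        return tuple(self.concepts[concept_id])

    def canonical(self, concept_id: str) -> str:
        """First-listed synonym, used as the 'textbook' term."""
        return self.concepts[concept_id][0]

    @classmethod
    def from_json(cls, path: str | Path) -> "ConceptLexicon":
        with open(path) as fh:
            raw = json.load(fh)
        return cls({cid: tuple(terms) for cid, terms in raw.items()})

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps({c: list(t) for c, t in self.concepts.items()}, indent=1)
        )
        return path


@dataclass(frozen=True)
class SyntheticDoc:
    """A document as a bag of lower-case terms."""

    doc_id: str
    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError(f"document {self.doc_id!r} is empty")


def generate_corpus(
    lexicon: ConceptLexicon,
    n_docs: int,
    doc_length: int = 40,
    seed: int = 0,
    background_rate: float = 0.3,
    background_vocab_size: int = 200,
    concept_weights: Mapping[str, float] | None = None,
) -> list[SyntheticDoc]:
    """Term-bag documents, each focused on one (weighted-random) concept.

    Every position in a document draws, independently, a uniform synonym
    of the focal concept with probability ``1 − background_rate`` and a
    generic background term otherwise.
    """
    if n_docs < 1:
        raise ValueError("n_docs must be >= 1")
    if not lexicon.concepts:
        raise ValueError("lexicon is empty")
    rng = np.random.default_rng(seed)
    concept_ids = sorted(lexicon.concepts)
    if concept_weights is None:
        p = None
    else:
        w = np.array([concept_weights.get(c, 0.0) for c in concept_ids], dtype=float)
        if w.sum() <= 0:
            raise ValueError("concept_weights sum to zero")
        p = w / w.sum()
    background = [f"bg{i:03d}" for i in range(background_vocab_size)]
    width = len(str(n_docs))
    docs: list[SyntheticDoc] = []
    for i in range(n_docs):
        focal = concept_ids[rng.choice(len(concept_ids), p=p)]
        syns = lexicon.synonyms(focal)
        terms = tuple(
            syns[rng.integers(len(syns))]
            if rng.random() >= background_rate
            else background[rng.integers(len(background))]
            for _ in range(doc_length)
        )
        docs.append(SyntheticDoc(doc_id=f"D{i:0{width}d}", terms=terms))
    return docs


# ---------------------------------------------------------------------------
# toy search engine


class CorpusIndex:
    """Inverted TF/DF index over a term-bag corpus."""

    def __init__(self, corpus: Sequence[SyntheticDoc]):
        self.n_docs = len(corpus)
        self.tf: dict[str, dict[str, int]] = {}
        self.doc_ids = [d.doc_id for d in corpus]
        for doc in corpus:
            for term in doc.terms:
                self.tf.setdefault(term, {})
                self.tf[term][doc.doc_id] = self.tf[term].get(doc.doc_id, 0) + 1

    def idf(self, term: str) -> float:
        df = len(self.tf.get(term, {}))
        return log(self.n_docs / df) if df else 0.0


def retrieve(
    term_set: frozenset[str] | set[str],
    corpus: Sequence[SyntheticDoc] | CorpusIndex,
    k: int = 10,
) -> list[str]:
    """Top-k doc ids by summed TF×IDF over the query terms.

    IDF = log(N/df); zero-scoring documents are excluded; ties break by
    ascending doc_id so rankings are reproducible.
    """
    if not term_set:
        raise QconvError("cannot retrieve with an empty query")
    index = corpus if isinstance(corpus, CorpusIndex) else CorpusIndex(corpus)
    scores: dict[str, float] = {}
    for term in term_set:
        idf = index.idf(term)
        if idf == 0.0 and term not in index.tf:
            continue
        for doc_id, tf in index.tf.get(term, {}).items():
            scores[doc_id] = scores.get(doc_id, 0.0) + tf * idf
    ranked = sorted(
        (d for d, s in scores.items() if s > 0),
        key=lambda d: (-scores[d], d),
    )
    return ranked[:k]


def expand_query(
    term_set: frozenset[str] | set[str], lexicon: ConceptLexicon
) -> frozenset[str]:
    """Replace each recognized term with its concept's full synonym list.

    Unknown terms pass through unchanged; the result is the union, so the
    operation is idempotent.
    """
    out: set[str] = set()
    for term in term_set:
        cid = lexicon.concept_of(term)
        out.update(lexicon.synonyms(cid) if cid else {term})
    return frozenset(out)


# ---------------------------------------------------------------------------
# study configuration


@dataclass(frozen=True)
class DifficultyParams:
    """The three behavioral knobs a difficulty level maps onto."""

    divergence: float  # P(user picks a non-canonical synonym per concept)
    noise: float  # P(query carries an off-target term)
    edit: float  # P(user edits the query at each later submission)

    def __post_init__(self) -> None:
        for name in ("divergence", "noise", "edit"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


DIFFICULTY_PRESETS: dict[str, DifficultyParams] = {
    "low": DifficultyParams(divergence=0.15, noise=0.10, edit=0.10),
    "medium": DifficultyParams(divergence=0.50, noise=0.15, edit=0.20),
    "high": DifficultyParams(divergence=0.85, noise=0.35, edit=0.40),
}


@dataclass(frozen=True)
class ScenarioSpec:
    """One search task: its target concepts and difficulty parameters."""

    scenario_id: int
    target_concepts: tuple[str, ...]
    difficulty: str = "medium"
    params: DifficultyParams | None = None

    def resolved_params(self) -> DifficultyParams:
        return self.params if self.params is not None else DIFFICULTY_PRESETS[self.difficulty]


@dataclass(frozen=True)
class SimConfig:
    """Whole-study simulation configuration.

    Defaults mirror the study shape: 33 users × 5 scenarios whose
    difficulty sequence is medium, low, medium, high, medium.
    """

    n_users: int = 33
    scenarios: tuple[ScenarioSpec, ...] = ()
    n_docs: int = 400
    doc_length: int = 40
    k: int = 10
    background_rate: float = 0.3
    noise_expansion: bool = True  # error-prone mapper may expand a spurious concept
    trailing_off_prob: float = 0.2  # chance of a final off-flagged resubmission
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_users < 1 or self.n_docs < 1 or self.k < 1:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.background_rate <= 1.0:
            raise ValueError("background_rate must lie in [0, 1]")
        if not 0.0 <= self.trailing_off_prob <= 1.0:
            raise ValueError("trailing_off_prob must lie in [0, 1]")
        if not self.scenarios:
            object.__setattr__(self, "scenarios", default_scenarios())

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = json.load(fh)
        scenarios = tuple(
            ScenarioSpec(
                scenario_id=int(s["scenario_id"]),
                target_concepts=tuple(s["target_concepts"]),
                difficulty=s.get("difficulty", "medium"),
                params=DifficultyParams(**s["params"]) if "params" in s else None,
            )
            for s in raw.pop("scenarios", [])
        )
        return cls(scenarios=scenarios, **raw)


def default_lexicon() -> ConceptLexicon:
    """Toy clinical lexicon: 12 concepts, 4 synonym terms each."""
    return ConceptLexicon(
        {
            "concussion": ("concussion", "mtbi", "head-injury", "brain-trauma"),
            "car_accident": ("mva", "car-accident", "crash", "collision"),
            "breast_cancer": ("dcis", "breast-cancer", "intraductal-carcinoma", "breast-neoplasm"),
            "noninvasive": ("noninvasive", "non-invasive", "in-situ", "localized"),
            "smoking": ("smoker", "smoking", "tobacco", "nicotine"),
            "ptsd": ("ptsd", "posttraumatic-stress", "combat-stress", "trauma-disorder"),
            "herbal": ("herbal", "supplement", "botanical", "phytotherapy"),
            "weight_loss": ("weight-loss", "slimming", "diet-aid", "anorexiant"),
            "mononucleosis": ("mono", "mononucleosis", "ebv", "glandular-fever"),
            "splenomegaly": ("splenomegaly", "enlarged-spleen", "spleen-swelling", "big-spleen"),
            "hypertension": ("hypertension", "high-blood-pressure", "htn", "elevated-bp"),
            "diabetes": ("diabetes", "dm2", "hyperglycemia", "insulin-resistance"),
        }
    )


def default_scenarios() -> tuple[ScenarioSpec, ...]:
    return (
        ScenarioSpec(1, ("concussion", "car_accident"), "medium"),
        ScenarioSpec(2, ("breast_cancer", "noninvasive"), "low"),
        ScenarioSpec(3, ("smoking", "ptsd"), "medium"),
        ScenarioSpec(4, ("herbal", "weight_loss"), "high"),
        ScenarioSpec(5, ("mononucleosis", "splenomegaly"), "medium"),
    )


# ---------------------------------------------------------------------------
# user simulation


def _pick_synonym(
    concept_id: str, lexicon: ConceptLexicon, divergence: float, rng: np.random.Generator
) -> str:
    syns = lexicon.synonyms(concept_id)
    if len(syns) > 1 and rng.random() < divergence:
        return syns[1 + rng.integers(len(syns) - 1)]
    return syns[0]


def _fmt_time(seconds: int) -> str:
    seconds %= 86400
    return f"{seconds // 3600:02d}:{(seconds % 3600) // 60:02d}:{seconds % 60:02d}"


def simulate_session(
    user_id: str,
    scenario: ScenarioSpec,
    lexicon: ConceptLexicon,
    corpus: Sequence[SyntheticDoc] | CorpusIndex,
    config: SimConfig,
    seed: int,
) -> list[QueryLogRecord]:
    """One user's off-then-on search session for one scenario.

    The user drafts a query from the scenario's target concepts (synonym
    choice governed by divergence, an off-target term added with the noise
    probability), submits it 1–5 times with the recommender off — editing
    between submissions only with the edit probability — then 1–3 times
    with it on. On-phase retrieval expands the query first; off-phase does
    not. When ``noise_expansion`` is enabled, the toy concept mapper is
    error-prone: with the scenario's noise probability it misreads this
    user's phrasing and additionally expands one unrelated concept's full
    synonym list (engine-internal, never visible in the logged query text
    — the route by which expansion can *spread* result sets apart). A
    final off-flagged resubmission occurs with a small probability,
    mimicking users toggling the feature at the end of a session.
    """
    if not scenario.target_concepts:
        raise QconvError(f"scenario {scenario.scenario_id} has no target concepts")
    params = scenario.resolved_params()
    rng = np.random.default_rng(seed)
    index = corpus if isinstance(corpus, CorpusIndex) else CorpusIndex(corpus)

    terms: list[str] = [
        _pick_synonym(c, lexicon, params.divergence, rng)
        for c in scenario.target_concepts
    ]
    off_target = sorted(set(lexicon.concepts) - set(scenario.target_concepts))
    noise_term: str | None = None
    if off_target and rng.random() < params.noise:
        noise_concept = off_target[rng.integers(len(off_target))]
        syns = lexicon.synonyms(noise_concept)
        noise_term = syns[rng.integers(len(syns))]
    spurious_concept: str | None = None
    if config.noise_expansion and off_target and rng.random() < params.noise:
        spurious_concept = off_target[rng.integers(len(off_target))]

    def current_query() -> str:
        return " ".join(terms + ([noise_term] if noise_term else []))

    def maybe_edit() -> None:
        nonlocal noise_term
        if rng.random() >= params.edit:
            return
        i = rng.integers(len(terms))
        terms[i] = _pick_synonym(scenario.target_concepts[i], lexicon, params.divergence, rng)
        if off_target and rng.random() < params.noise:
            if noise_term is None:
                nc = off_target[rng.integers(len(off_target))]
                syns = lexicon.synonyms(nc)
                noise_term = syns[rng.integers(len(syns))]
            else:
                noise_term = None

    n_off = int(rng.integers(1, 6))
    n_on = int(rng.integers(1, 4))
    phases = ["Off"] * n_off + ["On"] * n_on
    if rng.random() < config.trailing_off_prob:
        phases.append("Off")

    clock = int(9 * 3600 + rng.integers(0, 6 * 3600))
    records: list[QueryLogRecord] = []
    for seq, phase in enumerate(phases, start=1):
        if seq > 1:
            maybe_edit()
        query = current_query()
        qterms = frozenset(query.split())
        if phase == "On":
            search_terms = expand_query(qterms, lexicon)
            if spurious_concept is not None:
                search_terms |= frozenset(lexicon.synonyms(spurious_concept))
        else:
            search_terms = qterms
        docs = tuple(retrieve(search_terms, index, MAX_LOGGED_RESULTS))
        records.append(
            QueryLogRecord(
                log_id=f"L{user_id}S{scenario.scenario_id}Q{seq:02d}",
                user_id=user_id,
                scenario_id=scenario.scenario_id,
                seq=seq,
                query_text=query,
                sbqr_on=(phase == "On"),
                timestamp=_fmt_time(clock),
                retrieved_doc_ids=docs,
            )
        )
        clock += int(rng.integers(20, 120))
    return records


def generate_log(
    config: SimConfig | None = None, lexicon: ConceptLexicon | None = None
) -> list[QueryLogRecord]:
    """Full-study log: every user crossed with every scenario, seeded."""
    config = config or SimConfig()
    lexicon = lexicon or default_lexicon()
    corpus = generate_corpus(
        lexicon,
        n_docs=config.n_docs,
        doc_length=config.doc_length,
        seed=config.seed,
        background_rate=config.background_rate,
    )
    index = CorpusIndex(corpus)
    master = np.random.default_rng(config.seed)
    session_seeds = master.integers(0, 2**31 - 1, size=config.n_users * len(config.scenarios))
    records: list[QueryLogRecord] = []
    i = 0
    for u in range(1, config.n_users + 1):
        user_id = f"U{u:03d}"
        for scenario in config.scenarios:
            records.extend(
                simulate_session(
                    user_id, scenario, lexicon, index, config, int(session_seeds[i])
                )
            )
            i += 1
    records = sort_records(records)
    validate_records(records)
    return records
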