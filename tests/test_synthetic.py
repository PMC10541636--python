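"""Toy SBQR engine and user simulator: determinism, oracles, mechanisms."""

import math
import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qconv.entropy_analysis import (
    build_result_distributions,
    entropy_difference_pct,
    shannon_entropy,
)
from qconv.errors import IntegrityError, QconvError
from qconv.query_selection import select_query_pairs
from qconv.synthetic_data import (
    ConceptLexicon,
    CorpusIndex,
    DifficultyParams,
    ScenarioSpec,
    SimConfig,
    default_lexicon,
    default_scenarios,
    expand_query,
    generate_corpus,
    generate_log,
    retrieve,
    simulate_session,
)


@st.composite
def lexicons(draw):
    n_concepts = draw(st.integers(1, 5))
    pool = [f"t{i:02d}" for i in range(30)]
    rng_idx = draw(st.permutations(range(30)))
    concepts, used = {}, 0
    for c in range(n_concepts):
        size = draw(st.integers(1, 4))
        terms = tuple(pool[rng_idx[used + j]] for j in range(size))
        used += size
        concepts[f"c{c}"] = terms
    return ConceptLexicon(concepts)


class TestConceptLexicon:
    def test_ambiguous_term_rejected(self):
        with pytest.raises(IntegrityError):
            ConceptLexicon({"a": ("shared", "x"), "b": ("shared",)})

    def test_json_round_trip(self, tmp_path):
        lex = default_lexicon()
        path = lex.to_json(tmp_path / "lex.json")
        assert ConceptLexicon.from_json(path).concepts == {
            c: tuple(t) for c, t in lex.concepts.items()
        }

    def test_concept_lookup(self):
        lex = default_lexicon()
        assert lex.concept_of("dcis") == "breast_cancer"
        assert lex.concept_of("unknown-term") is None


class TestGenerateCorpus:
    def test_deterministic_for_fixed_seed(self):
        lex = default_lexicon()
        assert generate_corpus(lex, 50, seed=4) == generate_corpus(lex, 50, seed=4)

    def test_single_concept_zero_background(self):
        lex = ConceptLexicon({"only": ("alpha", "beta")})
        for doc in generate_corpus(lex, 20, doc_length=10, seed=1, background_rate=0.0):
            assert set(doc.terms) <= {"alpha", "beta"}

    def test_concept_coverage_matches_weights(self):
        lex = ConceptLexicon({"a": ("a1",), "b": ("b1",), "c": ("c1",)})
        weights = {"a": 0.6, "b": 0.3, "c": 0.1}
        docs = generate_corpus(
            lex, 5000, doc_length=5, seed=9, background_rate=0.0, concept_weights=weights
        )
        for cid, w in weights.items():
            frac = sum(d.terms[0].startswith(cid) for d in docs) / len(docs)
            se = math.sqrt(w * (1 - w) / len(docs))
            assert abs(frac - w) < 2 * se + 1e-9

    def test_zero_docs_rejected(self):
        with pytest.raises(ValueError):
            generate_corpus(default_lexicon(), 0)


class TestExpandQuery:
    def test_known_terms_expand_to_full_synonym_set(self):
        lex = ConceptLexicon({"hl": ("hearing-loss", "difficulty-of-hearing")})
        expanded = expand_query(frozenset({"hearing-loss"}), lex)
        assert expanded == {"hearing-loss", "difficulty-of-hearing"}

    def test_unknown_terms_pass_through(self):
        assert expand_query(frozenset({"zzz"}), default_lexicon()) == {"zzz"}

    @given(lexicons(), st.frozensets(st.sampled_from([f"t{i:02d}" for i in range(30)] + ["u1", "u2"]), min_size=1, max_size=6))
    @settings(max_examples=100)
    def test_idempotent_and_superset(self, lex, query):
        once = expand_query(query, lex)
        assert expand_query(once, lex) == once
        assert query <= once


class TestRetrieve:
    def test_single_matching_doc_ranked_first(self):
        lex = ConceptLexicon({"c": ("target",)})
        corpus = generate_corpus(lex, 5, doc_length=4, seed=2, background_rate=1.0)
        from qconv.synthetic_data import SyntheticDoc

        corpus.append(SyntheticDoc("D9", ("target", "target")))
        assert retrieve(frozenset({"target"}), corpus, k=3) == ["D9"]

    def test_tie_broken_by_ascending_doc_id(self):
        from qconv.synthetic_data import SyntheticDoc

        corpus = [
            SyntheticDoc("D2", ("x", "y")),
            SyntheticDoc("D1", ("x", "y")),
            SyntheticDoc("D3", ("z",)),
        ]
        assert retrieve(frozenset({"x"}), corpus, k=5) == ["D1", "D2"]

    def test_empty_query_rejected(self):
        with pytest.raises(QconvError):
            retrieve(frozenset(), [], k=5)

    def test_matches_exhaustive_score_and_sort_oracle(self):
        lex = default_lexicon()
        corpus = generate_corpus(lex, 200, doc_length=30, seed=6)
        n = len(corpus)
        rng = np.random.default_rng(13)
        all_terms = sorted({t for d in corpus for t in d.terms})
        for _ in range(25):
            query = frozenset(rng.choice(all_terms, size=3, replace=False))
            # independent brute-force scorer
            scores = {}
            for doc in corpus:
                s = 0.0
                for term in query:
                    tf = doc.terms.count(term)
                    df = sum(term in d.terms for d in corpus)
                    if tf and df:
                        s += tf * math.log(n / df)
                if s > 0:
                    scores[doc.doc_id] = s
            oracle = sorted(scores, key=lambda d: (-scores[d], d))[:10]
            assert retrieve(query, corpus, k=10) == oracle


def _uniform_scenarios(params):
    return tuple(
        ScenarioSpec(s.scenario_id, s.target_concepts, params=params)
        for s in default_scenarios()
    )


class TestSimulateSession:
    def _session(self, params, seed=0, **cfg_kwargs):
        lex = default_lexicon()
        cfg = SimConfig(n_users=1, n_docs=100, seed=seed, **cfg_kwargs)
        corpus = CorpusIndex(generate_corpus(lex, cfg.n_docs, cfg.doc_length, cfg.seed))
        scenario = ScenarioSpec(1, ("concussion", "car_accident"), params=params)
        return simulate_session("U001", scenario, lex, corpus, cfg, seed)

    def test_zero_edit_probability_preserves_query_text(self):
        for seed in range(10):
            records = self._session(DifficultyParams(0.6, 0.3, 0.0), seed=seed)
            offs = [r for r in records if not r.sbqr_on]
            ons = [r for r in records if r.sbqr_on]
            assert offs[0].query_text == ons[-1].query_text

    def test_zero_divergence_zero_noise_users_identical(self):
        texts = set()
        for seed in range(8):
            records = self._session(DifficultyParams(0.0, 0.0, 0.5), seed=seed)
            texts.add(records[0].query_text)
        assert len(texts) == 1

    def test_fixed_seed_reproduces_byte_identical_records(self):
        a = self._session(DifficultyParams(0.5, 0.2, 0.3), seed=5)
        b = self._session(DifficultyParams(0.5, 0.2, 0.3), seed=5)
        assert a == b

    def test_off_phase_then_on_phase_shape(self):
        records = self._session(DifficultyParams(0.5, 0.2, 0.3), seed=1)
        flags = [r.sbqr_on for r in records]
        assert flags[0] is False and True in flags
        # at most one trailing off-record after the on-phase
        on_last = max(i for i, f in enumerate(flags) if f)
        assert all(not f for f in flags[on_last + 1 :])
        assert len(flags[on_last + 1 :]) <= 1
        assert [r.seq for r in records] == list(range(1, len(records) + 1))

    def test_scenario_without_concepts_rejected(self):
        lex = default_lexicon()
        cfg = SimConfig(n_users=1, n_docs=50, seed=0)
        corpus = CorpusIndex(generate_corpus(lex, 50, seed=0))
        with pytest.raises(QconvError):
            simulate_session("U001", ScenarioSpec(1, ()), lex, corpus, cfg, 0)


class TestGenerateLog:
    def test_default_shape_has_165_groups(self, study_log):
        groups = {(r.user_id, r.scenario_id) for r in study_log}
        assert len(groups) == 33 * 5

    def test_every_group_yields_a_pair(self, study_log):
        pairs, excluded = select_query_pairs(study_log)
        assert len(pairs) == 165
        assert excluded == []

    def test_deterministic_for_fixed_seed(self, small_sim_config, small_log):
        assert generate_log(small_sim_config, default_lexicon()) == small_log


def _mean_entropy_diff(params, noise_expansion, seeds, n_users=33):
    lex = default_lexicon()
    diffs = []
    share_converged = []
    for seed in seeds:
        cfg = SimConfig(
            n_users=n_users,
            n_docs=200,
            doc_length=30,
            scenarios=_uniform_scenarios(params),
            noise_expansion=noise_expansion,
            seed=seed,
        )
        pairs, _ = select_query_pairs(generate_log(cfg, lex))
        off = build_result_distributions(pairs, "sbqr_off", k=10)
        on = build_result_distributions(pairs, "sbqr_on", k=10)
        for sid in off:
            d = entropy_difference_pct(
                shannon_entropy(off[sid]), shannon_entropy(on[sid])
            )
            diffs.append(d)
            share_converged.append(d <= 0)
    return statistics.fmean(diffs), statistics.fmean(share_converged)


class TestConvergenceMechanism:
    def test_synonym_divergence_is_collapsed_by_expansion(self):
        """High vocabulary divergence + clean expansion → entropy drops."""
        mean_diff, share = _mean_entropy_diff(
            DifficultyParams(divergence=0.5, noise=0.0, edit=0.0),
            noise_expansion=True,
            seeds=range(20),
        )
        assert mean_diff < 0
        assert share >= 0.9

    def test_noisy_expansion_without_divergence_cannot_converge(self):
        """No divergence to collapse + spurious expansions → entropy gains."""
        mean_diff, _ = _mean_entropy_diff(
            DifficultyParams(divergence=0.0, noise=0.15, edit=0.0),
            noise_expansion=True,
            seeds=range(20),
        )
        assert mean_diff >= 0
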