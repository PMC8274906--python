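"""Tokenization, TF-IDF keyword features and document embeddings."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.feature_extraction.text import TfidfVectorizer

from trialcease.text_features import (
    KeywordSpec,
    assemble_keyword_string,
    compute_tfidf,
    fit_keyword_spec,
    idf_value,
    infer_embedding,
    tfidf_matrix,
    tokenize,
    train_doc_embedding,
)


class TestTokenize:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("Coronavirus Infections", ["coronavirus", "infections"]),
            ("SARS-CoV-2", ["sars", "cov"]),
            ("COVID-19", ["covid"]),
            ("", []),
            ("120 kg", ["kg"]),
        ],
    )
    def test_examples(self, text, expected):
        assert tokenize(text) == expected

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.text(max_size=60))
    def test_tokens_are_lowercase_alnum_and_never_numeric(self, text):
        for token in tokenize(text):
            assert token == token.lower()
            assert token.isalnum()
            assert not token.isdigit()


class TestAssembleKeywordString:
    def test_dedup_keeps_first_occurrence(self, record_factory):
        record = record_factory(
            keywords=["COVID-19"],
            conditions=["COVID-19"],
            condition_mesh=["Coronavirus Infections"],
        )
        assert assemble_keyword_string(record) == "COVID-19,Coronavirus Infections"

    def test_all_empty(self, record_factory):
        assert assemble_keyword_string(record_factory()) == ""

    def test_field_order(self, record_factory):
        record = record_factory(
            keywords=["SARS-CoV-2 Infection"], condition_mesh=["Pneumonia"]
        )
        assert assemble_keyword_string(record) == "SARS-CoV-2 Infection,Pneumonia"


class TestTfidf:
    def test_idf_of_ubiquitous_term_is_one(self):
        assert idf_value(df=5, n=5) == pytest.approx(1.0, abs=1e-12)

    def test_idf_closed_form(self):
        assert idf_value(df=1, n=3) == pytest.approx(math.log(4 / 2) + 1, abs=1e-12)

    def test_idf_strictly_decreases_with_df(self):
        values = [idf_value(df, n=100) for df in range(0, 101)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_worked_example(self):
        docs = [["covid", "covid", "cytokine"], ["covid"], ["covid", "fever"]]
        spec = fit_keyword_spec(docs, top_k=10)
        vec = compute_tfidf(["covid", "covid", "cytokine"], spec)
        idf_cov = math.log(4 / 4) + 1
        idf_cyt = math.log(4 / 2) + 1
        raw = {"covid": 2 * idf_cov, "cytokine": 1 * idf_cyt}
        norm = math.hypot(*raw.values())
        by_term = dict(zip(spec.vocabulary, vec))
        assert by_term["covid"] == pytest.approx(raw["covid"] / norm, abs=1e-9)
        assert by_term["cytokine"] == pytest.approx(raw["cytokine"] / norm, abs=1e-9)
        assert by_term["covid"] == pytest.approx(0.7632, abs=1e-4)
        assert by_term["cytokine"] == pytest.approx(0.6461, abs=1e-4)

    def test_matches_sklearn_reference(self):
        rng = np.random.default_rng(0)
        alphabet = ["covid", "cytokine", "anxiety", "sars", "lung", "care"]
        docs = [
            [alphabet[i] for i in rng.integers(0, len(alphabet), size=rng.integers(1, 12))]
            for _ in range(20)
        ]
        spec = fit_keyword_spec(docs, top_k=len(alphabet))
        ours = tfidf_matrix(docs, spec)
        vectorizer = TfidfVectorizer(
            analyzer=lambda d: d, vocabulary=spec.vocabulary, norm="l2",
            smooth_idf=True, sublinear_tf=False,
        )
        reference = vectorizer.fit_transform(docs).toarray()
        np.testing.assert_allclose(ours, reference, atol=1e-12)

    def test_norm_is_unit_or_zero(self):
        docs = [["a", "b"], ["b", "c", "c"], ["a"]]
        spec = fit_keyword_spec(docs, top_k=3)
        for doc in docs + [["zzz"], []]:
            norm = np.linalg.norm(compute_tfidf(doc, spec))
            assert norm == pytest.approx(1.0, abs=1e-9) or norm == 0.0

    def test_out_of_vocabulary_doc_is_zero(self):
        spec = fit_keyword_spec([["a"], ["b"]], top_k=2)
        assert not compute_tfidf(["qq", "ww"], spec).any()

    def test_tie_break_keeps_lexicographically_smaller(self):
        docs = [["beta", "alpha"]] * 3
        spec = fit_keyword_spec(docs, top_k=1)
        assert spec.vocabulary == ["alpha"]

    def test_all_empty_docs_error(self):
        with pytest.raises(ValueError, match="empty"):
            fit_keyword_spec([[], []])

    def test_fit_never_sees_test_fold_terms(self):
        train = [["covid", "lung"], ["covid", "care"]]
        spec = fit_keyword_spec(train, top_k=10)
        assert "zanamivir" not in spec.df
        assert "zanamivir" not in spec.vocabulary

    def test_json_round_trip(self, tmp_path):
        spec = fit_keyword_spec([["a", "b"], ["b"]], top_k=2)
        spec.to_json(tmp_path / "spec.json")
        loaded = KeywordSpec.from_json(tmp_path / "spec.json")
        assert loaded == spec


def _topic_docs(stems, n, seed):
    rng = np.random.default_rng(seed)
    return [
        [stems[i] for i in rng.integers(0, len(stems), size=rng.integers(8, 16))]
        for _ in range(n)
    ]


class TestDocEmbedding:
    def test_dimensionality_and_finiteness(self):
        docs = _topic_docs(["cytokine", "storm", "plasma", "oxygen"], 12, seed=0)
        model = train_doc_embedding(docs, d=100, seed=1, epochs=5)
        vec = infer_embedding(model, docs[0])
        assert vec.shape == (100,)
        assert np.all(np.isfinite(vec))

    def test_training_is_deterministic(self):
        docs = _topic_docs(["cytokine", "storm", "plasma", "oxygen"], 10, seed=3)
        probe = docs[0]
        v1 = infer_embedding(train_doc_embedding(docs, d=16, seed=5, epochs=5), probe)
        v2 = infer_embedding(train_doc_embedding(docs, d=16, seed=5, epochs=5), probe)
        np.testing.assert_array_equal(v1, v2)

    def test_inference_is_repeatable(self):
        docs = _topic_docs(["anxiety", "stress", "survey", "mood"], 10, seed=4)
        model = train_doc_embedding(docs, d=16, seed=2, epochs=5)
        np.testing.assert_array_equal(
            infer_embedding(model, docs[3]), infer_embedding(model, docs[3])
        )

    def test_empty_description_is_zero_vector(self):
        docs = _topic_docs(["covid", "lung", "ward", "oxygen"], 10, seed=6)
        model = train_doc_embedding(docs, d=16, seed=2, epochs=5)
        assert not infer_embedding(model, []).any()
        assert not infer_embedding(model, ["fully", "unknown", "tokens"]).any()

    def test_all_empty_corpus_errors(self):
        with pytest.raises(ValueError, match="non-empty"):
            train_doc_embedding([[], [], []])

    def test_topically_disjoint_corpora_separate(self):
        """Within-topic cosine similarity exceeds between-topic similarity."""
        topic_a = _topic_docs(["cytokine", "storm", "prophylaxis", "hypoxemia", "worker"], 25, 7)
        topic_b = _topic_docs(["anxiety", "depression", "survey", "wellbeing", "mood"], 25, 8)
        model = train_doc_embedding(topic_a + topic_b, d=50, seed=1, epochs=20)
        vectors = np.array([infer_embedding(model, doc) for doc in topic_a + topic_b])
        norms = np.linalg.norm(vectors, axis=1, keepdims=True)
        unit = vectors / np.where(norms > 0, norms, 1.0)
        sims = unit @ unit.T
        n = len(topic_a)
        within = np.concatenate(
            [sims[:n, :n][np.triu_indices(n, 1)], sims[n:, n:][np.triu_indices(n, 1)]]
        )
        between = sims[:n, n:].ravel()
        assert within.mean() > between.mean()
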