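"""Keyword TF-IDF features and document-embedding features.

Keyword features come from the union of a trial's keyword, condition-MeSH
and condition fields, tokenized on punctuation/whitespace and scored with
smoothed-idf TF-IDF::

    tf-idf(f, T) = tf(f, T) * idf(f)          (raw in-document count tf)
    idf(f)       = ln((1 + n) / (1 + df(f))) + 1

followed by per-document L2 normalization.  The vocabulary keeps the top-k
terms by mean normalized TF-IDF over the fitting corpus (boundary ties
lexicographic) and is fitted on training folds only.

Embedding features are distributed-memory paragraph vectors trained on the
Detailed Description field; see :mod:`trialcease.doc_embedding`.
"""

from __future__ import annotations

import json
import math
import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .ctgov_io import TrialRecord
from .doc_embedding import (  # noqa: F401  (re-exported module surface)
    ParagraphVectorModel,
    infer_embedding,
    infer_embedding_matrix,
    train_doc_embedding,
)

_TOKEN_RE = re.compile(r"[^0-9A-Za-z]+")


def tokenize(text: str) -> list[str]:
    """Split on punctuation/whitespace, lowercase, drop purely numeric tokens.

    "SARS-CoV-2" tokenizes to ["sars", "cov"]: the hyphens split it and the
    trailing "2" is numeric.
    """
    return [
        tok.lower()
        for tok in _TOKEN_RE.split(text)
        if tok and not tok.isdigit()
    ]


def assemble_keyword_string(record: TrialRecord) -> str:
    """Comma-joined union of keywords, condition MeSH terms and conditions.

    Exact-string duplicates are removed keeping the first occurrence, in
    field order keywords -> condition MeSH -> conditions.
    """
    seen: set[str] = set()
    out: list[str] = []
    for term in record.keywords + record.condition_mesh + record.conditions:
        if term not in seen:
            seen.add(term)
            out.append(term)
    return ",".join(out)


def keyword_tokens(record: TrialRecord) -> list[str]:
    return tokenize(assemble_keyword_string(record))


@dataclass
class KeywordSpec:
    """Fitted TF-IDF vocabulary with document frequencies.

    ``vocabulary`` is ordered by mean normalized TF-IDF on the fitting corpus
    (descending, ties lexicographic); ``idf`` is aligned to it and always
    positive by the smoothed-idf construction.
    """

    vocabulary: list[str]
    df: dict[str, int]
    n_fit: int

    @property
    def idf(self) -> np.ndarray:
        return np.array([idf_value(self.df[t], self.n_fit) for t in self.vocabulary])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"vocabulary": self.vocabulary, "df": self.df, "n_fit": self.n_fit},
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "KeywordSpec":
        raw = json.loads(Path(path).read_text())
        return cls(vocabulary=raw["vocabulary"], df=raw["df"], n_fit=raw["n_fit"])


def idf_value(df: int, n: int) -> float:
    """Smoothed inverse document frequency: ln((1+n)/(1+df)) + 1."""
    return math.log((1 + n) / (1 + df)) + 1.0


def fit_keyword_spec(training_docs: list[list[str]], top_k: int = 500) -> KeywordSpec:
    """Fit df/idf and the top-k vocabulary on training documents only.

    Terms are ranked by their mean per-document L2-normalized TF-IDF over the
    fitting corpus (documents lacking a term contribute zero to its mean).
    """
    if not training_docs:
        raise ValueError("fit_keyword_spec requires at least one training document")
    if all(not doc for doc in training_docs):
        raise ValueError("fit_keyword_spec: all training documents are empty")
    n = len(training_docs)
    df: Counter = Counter()
    for doc in training_docs:
        df.update(set(doc))
    idf = {term: idf_value(count, n) for term, count in df.items()}
    score_sums: dict[str, float] = {term: 0.0 for term in df}
    for doc in training_docs:
        tf = Counter(doc)
        values = {term: count * idf[term] for term, count in tf.items()}
        norm = math.sqrt(sum(v * v for v in values.values()))
        if norm > 0:
            for term, v in values.items():
                score_sums[term] += v / norm
    ranked = sorted(df, key=lambda t: (-score_sums[t] / n, t))
    vocabulary = ranked[:top_k]
    return KeywordSpec(vocabulary=vocabulary, df={t: df[t] for t in vocabulary}, n_fit=n)


def compute_tfidf(doc: list[str], spec: KeywordSpec) -> np.ndarray:
    """L2-normalized TF-IDF vector aligned to ``spec.vocabulary``.

    Out-of-vocabulary tokens are ignored; an all-zero vector stays all-zero.
    """
    tf = Counter(doc)
    values = np.array([tf[t] for t in spec.vocabulary], dtype=float) * spec.idf
    norm = np.linalg.norm(values)
    return values / norm if norm > 0 else values


def tfidf_matrix(docs: list[list[str]], spec: KeywordSpec) -> np.ndarray:
    return np.array([compute_tfidf(doc, spec) for doc in docs])
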