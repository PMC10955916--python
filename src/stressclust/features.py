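"""Term-document counts, TF-IDF, vocabulary filtering and MI ranking.

TF-IDF uses raw term frequency, the smoothed inverse document frequency
``idf(t) = ln((1 + N) / (1 + df(t))) + 1`` and row-wise L2 normalization
(the scikit-learn convention).  On the normalized weights two pruning
rules remove uninformative words:

* rule (i), *rare*:   a word's total weight over all documents must be
  at least ``tau_total`` (default 0.5);
* rule (ii), *common*: the ratio of its maximum weight to its total
  weight must be at least ``tau_ratio`` (default 0.1) — a word spread
  evenly over many documents has a small ratio and is discarded.

Both thresholds depend on the TF-IDF variant, so they are configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from sklearn.feature_extraction.text import TfidfTransformer
from sklearn.metrics import mutual_info_score

from .corpus import Corpus

__all__ = [
    "TermDocumentMatrix",
    "TfidfMatrix",
    "FilterThresholds",
    "FilterResult",
    "FeatureRanking",
    "build_term_document_matrix",
    "compute_tfidf",
    "filter_terms",
    "rank_terms_by_mutual_information",
    "select_top_fraction",
    "restrict_vocabulary",
]


@dataclass(frozen=True)
class TermDocumentMatrix:
    counts: np.ndarray  # documents x terms, nonnegative integers
    vocabulary: tuple[str, ...]
    doc_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.doc_ids), len(self.vocabulary)):
            raise ValueError("counts shape inconsistent with vocabulary/doc_ids")
        if len(set(self.vocabulary)) != len(self.vocabulary):
            raise ValueError("vocabulary entries must be unique")
        if (self.counts.sum(axis=0) == 0).any():
            raise ValueError("all-zero term column")


@dataclass(frozen=True)
class TfidfMatrix:
    """Row-normalized TF-IDF weights plus the per-term filter statistics."""

    weights: np.ndarray  # documents x terms, nonnegative
    vocabulary: tuple[str, ...]
    doc_ids: tuple[str, ...]
    idf: np.ndarray

    @property
    def total_weight(self) -> np.ndarray:
        return self.weights.sum(axis=0)

    @property
    def max_weight(self) -> np.ndarray:
        return self.weights.max(axis=0) if self.weights.size else np.zeros(0)

    @property
    def n_documents(self) -> int:
        return len(self.doc_ids)

    @property
    def n_terms(self) -> int:
        return len(self.vocabulary)


def build_term_document_matrix(corpus: Corpus) -> TermDocumentMatrix:
    """Count token occurrences; vocabulary is sorted lexicographically."""
    vocab = sorted({tok for doc in corpus for tok in doc.tokens})
    if not vocab:
        raise ValueError("corpus has no tokens; run preprocessing first")
    index = {t: j for j, t in enumerate(vocab)}
    counts = np.zeros((len(corpus), len(vocab)), dtype=np.int64)
    for i, doc in enumerate(corpus):
        for tok in doc.tokens:
            counts[i, index[tok]] += 1
    return TermDocumentMatrix(counts, tuple(vocab), corpus.ids)


def compute_tfidf(tdm: TermDocumentMatrix) -> TfidfMatrix:
    transformer = TfidfTransformer(norm="l2", smooth_idf=True, sublinear_tf=False)
    weights = transformer.fit_transform(sparse.csr_matrix(tdm.counts)).toarray()
    return TfidfMatrix(weights, tdm.vocabulary, tdm.doc_ids, transformer.idf_.copy())


@dataclass(frozen=True)
class FilterThresholds:
    tau_total: float = 0.5
    tau_ratio: float = 0.1

    def __post_init__(self) -> None:
        if self.tau_total < 0:
            raise ValueError("tau_total must be >= 0")
        if not 0 <= self.tau_ratio <= 1:
            raise ValueError("tau_ratio must be in [0, 1]")


@dataclass(frozen=True)
class FilterResult:
    tfidf: TfidfMatrix
    discarded: dict[str, str] = field(default_factory=dict)  # term -> "rare" | "common"


def filter_terms(
    tfidf: TfidfMatrix, thresholds: FilterThresholds = FilterThresholds()
) -> FilterResult:
    """Apply the two pruning rules; surviving columns keep their weights.

    A term survives iff ``total_weight >= tau_total`` and
    ``max_weight / total_weight >= tau_ratio``.  Rule (i) failures are
    recorded as ``"rare"``, remaining rule (ii) failures as ``"common"``.
    No renormalization is applied afterwards.
    """
    total = tfidf.total_weight
    ratio = np.divide(
        tfidf.max_weight, total, out=np.zeros_like(total), where=total > 0
    )
    rare = total < thresholds.tau_total
    common = ~rare & (ratio < thresholds.tau_ratio)
    keep = ~rare & ~common
    if not keep.any():
        raise ValueError(
            "all terms discarded by the filter rules; relax tau_total/tau_ratio"
        )
    discarded = {}
    for j, term in enumerate(tfidf.vocabulary):
        if rare[j]:
            discarded[term] = "rare"
        elif common[j]:
            discarded[term] = "common"
    kept_idx = np.flatnonzero(keep)
    restricted = TfidfMatrix(
        tfidf.weights[:, kept_idx],
        tuple(tfidf.vocabulary[j] for j in kept_idx),
        tfidf.doc_ids,
        tfidf.idf[kept_idx],
    )
    return FilterResult(restricted, discarded)


@dataclass(frozen=True)
class FeatureRanking:
    """Terms ordered by descending mutual information with the label (bits)."""

    terms: tuple[str, ...]
    scores: np.ndarray

    def __post_init__(self) -> None:
        if len(self.terms) != len(self.scores):
            raise ValueError("terms and scores length mismatch")


def rank_terms_by_mutual_information(
    tfidf: TfidfMatrix, labels
) -> FeatureRanking:
    """Rank terms by plug-in MI between presence (weight > 0) and the label.

    MI is estimated from the empirical 2x2 contingency table and reported
    in bits; ties break lexicographically by term.
    """
    labels = np.asarray(labels)
    if labels.shape != (tfidf.n_documents,):
        raise ValueError("labels length must equal number of documents")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to rank by MI")
    present = tfidf.weights > 0
    scores = np.array(
        [mutual_info_score(labels, present[:, j]) / math.log(2) for j in range(tfidf.n_terms)]
    )
    order = sorted(range(tfidf.n_terms), key=lambda j: (-scores[j], tfidf.vocabulary[j]))
    return FeatureRanking(
        tuple(tfidf.vocabulary[j] for j in order), scores[list(order)]
    )


def select_top_fraction(ranking: FeatureRanking, fraction: float) -> tuple[str, ...]:
    """Return the top ``ceil(fraction * n_terms)`` terms of the ranking."""
    if not ranking.terms:
        raise ValueError("ranking is empty")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = math.ceil(fraction * len(ranking.terms))
    return ranking.terms[:n]


def restrict_vocabulary(tfidf: TfidfMatrix, terms) -> TfidfMatrix:
    """Restrict a TF-IDF matrix to a term subset (original column order)."""
    wanted = set(terms)
    unknown = wanted - set(tfidf.vocabulary)
    if unknown:
        raise KeyError(f"terms not in vocabulary: {sorted(unknown)[:5]}")
    idx = [j for j, t in enumerate(tfidf.vocabulary) if t in wanted]
    return TfidfMatrix(
        tfidf.weights[:, idx],
        tuple(tfidf.vocabulary[j] for j in idx),
        tfidf.doc_ids,
        tfidf.idf[idx],
    )
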