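"""Cluster-label matching, accuracy metrics and the word-fraction protocol.

Cluster ids from unsupervised consensus carry no meaning, so evaluation
first picks the cluster-to-label permutation that maximizes accuracy and
reports the confusion matrix under that mapping.  Naming follows the
study convention this package targets: "positive" is the *low*-stress
class and "negative" the *high*-stress class — the reverse of the usual
clinical convention, so the fields are named ``tpr_low`` / ``tnr_high``
to keep that explicit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import Corpus
from .features import (
    FilterThresholds,
    build_term_document_matrix,
    compute_tfidf,
    filter_terms,
    rank_terms_by_mutual_information,
    restrict_vocabulary,
    select_top_fraction,
)

__all__ = [
    "ConfusionMatrix2x2",
    "MetricsReport",
    "FractionCurve",
    "match_clusters_to_labels",
    "compute_metrics",
    "word_fraction_experiment",
    "DEFAULT_FRACTIONS",
]

DEFAULT_FRACTIONS = tuple(round(0.1 * i, 1) for i in range(1, 11))


@dataclass(frozen=True)
class ConfusionMatrix2x2:
    """Rows = clusters (after label matching), columns = labels (low, high)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (2, 2) or (c < 0).any():
            raise ValueError("confusion matrix must be 2x2 nonnegative")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float  # percent
    tpr_low: float  # percent, correct among low-stress (label 0)
    tnr_high: float  # percent, correct among high-stress (label 1)
    mapping: tuple[int, int]  # cluster index -> label
    confusion: ConfusionMatrix2x2

    def to_dict(self) -> dict:
        return {
            "accuracy_pct": round(float(self.accuracy), 2),
            "tpr_low_pct": round(float(self.tpr_low), 2),
            "tnr_high_pct": round(float(self.tnr_high), 2),
            "mapping": [int(m) for m in self.mapping],
            "confusion_matrix": self.confusion.counts.tolist(),
        }


def match_clusters_to_labels(assignment, labels):
    """Find the accuracy-maximizing cluster-to-label permutation.

    Returns ``(ConfusionMatrix2x2, mapping)`` where ``mapping[c]`` is the
    label matched to cluster ``c``; ties keep the identity mapping.  The
    matrix rows are reordered so its diagonal counts the matched documents.
    """
    assignment = np.asarray(assignment)
    labels = np.asarray(labels)
    if assignment.shape != labels.shape:
        raise ValueError("assignment and labels must have equal length")
    if len(labels) == 0 or not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary (0/1) and nonempty")
    raw = np.zeros((2, 2), dtype=np.int64)
    for a, y in zip(assignment, labels):
        raw[int(a), int(y)] += 1
    acc_identity = raw[0, 0] + raw[1, 1]
    acc_swap = raw[0, 1] + raw[1, 0]
    if acc_swap > acc_identity:
        return ConfusionMatrix2x2(raw[::-1]), (1, 0)
    return ConfusionMatrix2x2(raw), (0, 1)


def compute_metrics(
    cm: ConfusionMatrix2x2, mapping: tuple[int, int] = (0, 1)
) -> MetricsReport:
    """Accuracy and the per-class rates from a matched confusion matrix.

    ``tpr_low`` is the fraction of low-stress documents in the matched
    low cluster; ``tnr_high`` the fraction of high-stress documents in the
    matched high cluster.  All values in percent.
    """
    c = cm.counts
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    low_total = c[0, 0] + c[1, 0]
    high_total = c[0, 1] + c[1, 1]
    if low_total == 0 or high_total == 0:
        raise ValueError("a label column is empty; per-class rate undefined")
    return MetricsReport(
        accuracy=100.0 * (c[0, 0] + c[1, 1]) / cm.total,
        tpr_low=100.0 * c[0, 0] / low_total,
        tnr_high=100.0 * c[1, 1] / high_total,
        mapping=mapping,
        confusion=cm,
    )


@dataclass(frozen=True)
class FractionCurve:
    """Matched accuracy as a function of the MI-top word fraction used."""

    fractions: tuple[float, ...]
    accuracies: tuple[float, ...]  # percent; NaN marks an unusable fraction

    def __post_init__(self) -> None:
        if len(self.fractions) != len(self.accuracies):
            raise ValueError("fractions and accuracies length mismatch")
        if list(self.fractions) != sorted(set(self.fractions)):
            raise ValueError("fractions must be strictly increasing")


def word_fraction_experiment(
    corpus: Corpus,
    labels,
    config=None,
    fractions=DEFAULT_FRACTIONS,
    thresholds: FilterThresholds = FilterThresholds(),
) -> FractionCurve:
    """Rerun the whole pipeline on MI-top word subsets of growing size.

    Words surviving the filter rules are ranked by mutual information
    with the label; for each fraction the vocabulary is restricted to the
    top slice and the ensemble, consensus and assignment are recomputed
    with the same ``seed_base``.  When a slice has fewer terms than
    ``n_topics`` the topic count is clamped to the slice size; a fraction
    under which fewer documents than clusters retain any nonzero weight
    is recorded as NaN.
    """
    from dataclasses import replace

    from .ensemble import EnsembleConfig, TopicEnsembleModel

    if config is None:
        config = EnsembleConfig()
    labels = np.asarray(labels)
    tfidf = compute_tfidf(build_term_document_matrix(corpus))
    filtered = filter_terms(tfidf, thresholds).tfidf
    ranking = rank_terms_by_mutual_information(filtered, labels)
    accuracies = []
    for fraction in fractions:
        terms = select_top_fraction(ranking, fraction)
        sub = restrict_vocabulary(filtered, terms)
        nonzero_docs = int((sub.weights.sum(axis=1) > 0).sum())
        if nonzero_docs < config.n_clusters:
            accuracies.append(float("nan"))
            continue
        k = min(config.n_topics, sub.n_terms, sub.n_documents)
        run_config = config if k == config.n_topics else replace(config, n_topics=k)
        results = TopicEnsembleModel(sub, run_config).fit()
        accuracies.append(results.evaluate(labels).accuracy)
    return FractionCurve(tuple(fractions), tuple(accuracies))
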