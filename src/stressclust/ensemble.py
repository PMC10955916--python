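"""Two-phase topic-ensemble consensus clustering.

Phase 1 fits non-negative matrix factorization (NMF) to the filtered
TF-IDF matrix ``V`` (documents x terms) under ``S`` different random
seeds, ``k`` topics each.  NMF decomposes ``V ~= W H`` with nonnegative
factors: rows of ``H`` are topics over the vocabulary, rows of ``W`` are
per-document topic loadings.  Because the factorization depends on the
random start, each seed yields a different topic set; the ``S x k``
L2-normalized topic vectors together form the ensemble (700 members at
the defaults ``S = 70``, ``k = 10``).

Phase 2 integrates the members with agglomerative hierarchical clustering
under complete linkage on cosine distance, cutting the tree at two
clusters.  Documents are then assigned to the cluster on which they carry
the larger total loading: within each run, ``W`` columns are rescaled by
the norm of the matching ``H`` row (so ``W H`` is unchanged) and ``W``
rows are L1-normalized, making every run contribute one unit of mass per
document; a document's cluster score is the sum of its normalized
loadings over the cluster's topics.

The model-object interface (:class:`TopicEnsembleModel` /
:class:`TopicEnsembleResults`) wraps these steps; the module functions
remain usable on their own.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .features import (
    FilterThresholds,
    TfidfMatrix,
    build_term_document_matrix,
    compute_tfidf,
    filter_terms,
)

__all__ = [
    "EnsembleConfig",
    "NmfRun",
    "TopicPool",
    "ConsensusResult",
    "fit_nmf",
    "generate_ensemble",
    "consensus_cluster",
    "assign_documents",
    "top_keywords",
    "TopicEnsembleModel",
    "TopicEnsembleResults",
]

_EPS = 1e-12


@dataclass(frozen=True)
class EnsembleConfig:
    """Knobs of the two-phase ensemble.

    ``n_topics`` (k) and ``n_seeds`` (S) default to the 10 x 70 = 700
    member configuration; ``seed_base`` shifts the whole seed range for
    reproducibility.  ``tol`` is the relative improvement of the Frobenius
    reconstruction error below which an NMF run stops.
    """

    n_topics: int = 10
    n_seeds: int = 70
    n_clusters: int = 2
    max_iter: int = 300
    tol: float = 1e-5
    seed_base: int = 0

    def __post_init__(self) -> None:
        if self.n_topics < 1 or self.n_seeds < 1:
            raise ValueError("n_topics and n_seeds must be >= 1")
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.n_clusters > self.n_topics * self.n_seeds:
            raise ValueError("n_clusters exceeds the ensemble size")


@dataclass(frozen=True)
class NmfRun:
    seed: int
    W: np.ndarray  # documents x k
    H: np.ndarray  # k x terms
    errors: tuple[float, ...]  # Frobenius error per recorded iteration

    @property
    def final_error(self) -> float:
        return self.errors[-1]


def fit_nmf(V, k: int, seed: int, config: EnsembleConfig = EnsembleConfig()) -> NmfRun:
    """Frobenius-norm NMF by multiplicative updates from a seeded start.

    ``W`` and ``H`` are initialized uniform on (0, 1]; the classical
    multiplicative updates keep both factors strictly positive and the
    reconstruction error non-increasing.  Deterministic for fixed
    ``(V, k, seed, config)``.
    """
    if isinstance(V, TfidfMatrix):
        V = V.weights
    V = np.asarray(V, dtype=np.float64)
    if V.ndim != 2:
        raise ValueError("V must be a 2-d matrix")
    if (V < 0).any():
        raise ValueError("V must be nonnegative")
    n, p = V.shape
    if k > min(n, p):
        raise ValueError(f"k={k} exceeds min(n_documents, n_terms)={min(n, p)}")
    rng = np.random.default_rng(seed)
    # 1 - random() maps [0, 1) to (0, 1]
    W = 1.0 - rng.random((n, k))
    H = 1.0 - rng.random((k, p))
    errors = [float(np.linalg.norm(V - W @ H))]
    for _ in range(config.max_iter):
        H *= (W.T @ V) / (W.T @ W @ H + _EPS)
        W *= (V @ H.T) / (W @ H @ H.T + _EPS)
        err = float(np.linalg.norm(V - W @ H))
        if not np.isfinite(err):
            raise ArithmeticError(f"NMF diverged (seed={seed})")
        prev = errors[-1]
        errors.append(err)
        if prev - err < config.tol * max(prev, _EPS):
            break
    return NmfRun(seed, W, H, tuple(errors))


@dataclass(frozen=True)
class TopicPool:
    """The pooled ensemble members with per-run document loadings.

    ``topics`` stacks every run's L2-normalized ``H`` rows; ``loadings``
    holds, per run, the ``W`` matrix after rescaling columns by the
    corresponding ``H`` row norms and L1-normalizing rows.  ``provenance``
    records ``(run_index, seed, topic_index)`` per pooled row.
    """

    topics: np.ndarray  # (S*k) x terms, unit rows
    loadings: tuple[np.ndarray, ...]  # S matrices, documents x k
    provenance: tuple[tuple[int, int, int], ...]
    doc_ids: tuple[str, ...]
    vocabulary: tuple[str, ...]

    @property
    def n_members(self) -> int:
        return self.topics.shape[0]


def generate_ensemble(
    tfidf: TfidfMatrix, config: EnsembleConfig = EnsembleConfig()
) -> TopicPool:
    """Run NMF under seeds ``seed_base .. seed_base + S - 1`` and pool topics."""
    topics = []
    loadings = []
    provenance = []
    for run in range(config.n_seeds):
        seed = config.seed_base + run
        try:
            result = fit_nmf(tfidf, config.n_topics, seed, config)
        except Exception as exc:
            raise RuntimeError(f"NMF run with seed {seed} failed: {exc}") from exc
        norms = np.linalg.norm(result.H, axis=1)
        safe = np.maximum(norms, _EPS)
        topics.append(result.H / safe[:, None])
        W_scaled = result.W * norms[None, :]
        row_mass = np.maximum(W_scaled.sum(axis=1, keepdims=True), _EPS)
        loadings.append(W_scaled / row_mass)
        provenance.extend((run, seed, j) for j in range(config.n_topics))
    return TopicPool(
        np.vstack(topics),
        tuple(loadings),
        tuple(provenance),
        tfidf.doc_ids,
        tfidf.vocabulary,
    )


def _complete_linkage(D: np.ndarray, n_clusters: int):
    """Naive agglomerative complete linkage on a precomputed distance matrix.

    Ties on merge distance break toward the pair with the smallest member
    indices (row-major scan).  Returns flat cluster labels and the merge
    history as ``(height, members_a, members_b)`` tuples.
    """
    n = D.shape[0]
    D = D.copy()
    np.fill_diagonal(D, np.inf)
    active = list(range(n))
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    history = []
    while len(active) > n_clusters:
        sub = D[np.ix_(active, active)]
        flat = int(np.argmin(sub))
        ai, aj = divmod(flat, len(active))
        if ai > aj:
            ai, aj = aj, ai
        a, b = active[ai], active[aj]
        height = float(sub[ai, aj])
        history.append((height, tuple(members[a]), tuple(members[b])))
        # complete linkage: distance to the merged cluster is the max
        for other in active:
            if other not in (a, b):
                D[a, other] = D[other, a] = max(D[a, other], D[b, other])
        members[a] = members[a] + members[b]
        del members[b]
        active.remove(b)
    labels = np.empty(n, dtype=np.int64)
    for new_id, a in enumerate(sorted(active)):
        labels[members[a]] = new_id
    return labels, tuple(history)


def consensus_cluster(pool: TopicPool, config: EnsembleConfig = EnsembleConfig()):
    """Cluster the pooled topics (cosine distance, complete linkage).

    Returns ``(topic_cluster, linkage_record)`` where ``topic_cluster``
    assigns each pooled topic to one of ``n_clusters`` groups.
    """
    if pool.n_members < config.n_clusters:
        raise ValueError("fewer pooled topics than requested clusters")
    T = pool.topics
    D = 1.0 - T @ T.T  # rows are unit vectors
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, None)
    off = D[~np.eye(len(D), dtype=bool)]
    if config.n_clusters > 1 and off.size and off.max() < 1e-12:
        raise ValueError("degenerate topic pool: all topics identical")
    return _complete_linkage(D, config.n_clusters)


def assign_documents(
    pool: TopicPool,
    topic_cluster: np.ndarray,
    config: EnsembleConfig = EnsembleConfig(),
    linkage_record=(),
) -> "ConsensusResult":
    """Score documents against topic clusters and assign by argmax.

    Each run contributes its L1-normalized loading row, so a document's
    scores across clusters sum to the number of runs; ties go to the
    lower cluster index.
    """
    topic_cluster = np.asarray(topic_cluster)
    if topic_cluster.shape != (pool.n_members,):
        raise ValueError("topic_cluster must cover every pooled topic")
    n_docs = len(pool.doc_ids)
    n_clusters = int(topic_cluster.max()) + 1
    doc_scores = np.zeros((n_docs, n_clusters))
    k = pool.loadings[0].shape[1]
    for run, W in enumerate(pool.loadings):
        for j in range(k):
            doc_scores[:, topic_cluster[run * k + j]] += W[:, j]
    assignment = doc_scores.argmax(axis=1)
    return ConsensusResult(
        topic_cluster=topic_cluster,
        doc_scores=doc_scores,
        assignment=assignment,
        linkage_record=tuple(linkage_record),
        doc_ids=pool.doc_ids,
    )


@dataclass(frozen=True)
class ConsensusResult:
    topic_cluster: np.ndarray
    doc_scores: np.ndarray  # documents x n_clusters
    assignment: np.ndarray
    linkage_record: tuple
    doc_ids: tuple[str, ...]

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.doc_scores.shape[1])


def top_keywords(topic: np.ndarray, vocabulary: Sequence[str], n: int = 10) -> list[str]:
    """The ``n`` heaviest terms of a topic, descending; ties lexicographic."""
    if n > len(vocabulary):
        raise ValueError("n exceeds vocabulary size")
    order = sorted(range(len(vocabulary)), key=lambda j: (-topic[j], vocabulary[j]))
    return [vocabulary[j] for j in order[:n]]


class TopicEnsembleModel:
    """Ensemble topic-clustering model over a (filtered) TF-IDF matrix.

    Parameters
    ----------
    tfidf:
        Document x term TF-IDF weights, normally after vocabulary
        filtering.
    config:
        Ensemble settings; defaults reproduce the 70-seed, 10-topic,
        2-cluster configuration.
    """

    def __init__(self, tfidf: TfidfMatrix, config: Optional[EnsembleConfig] = None, **overrides):
        if config is None:
            config = EnsembleConfig(**overrides)
        elif overrides:
            config = replace(config, **overrides)
        self.tfidf = tfidf
        self.config = config

    @classmethod
    def from_corpus(
        cls,
        corpus,
        thresholds: FilterThresholds = FilterThresholds(),
        config: Optional[EnsembleConfig] = None,
        **overrides,
    ) -> "TopicEnsembleModel":
        """Build the model from a preprocessed corpus (counts -> TF-IDF -> filter)."""
        tfidf = compute_tfidf(build_term_document_matrix(corpus))
        filtered = filter_terms(tfidf, thresholds).tfidf
        model = cls(filtered, config, **overrides)
        model.labels_ = corpus.labels
        return model

    def fit(self) -> "TopicEnsembleResults":
        pool = generate_ensemble(self.tfidf, self.config)
        topic_cluster, record = consensus_cluster(pool, self.config)
        consensus = assign_documents(pool, topic_cluster, self.config, record)
        return TopicEnsembleResults(self, pool, consensus)


class TopicEnsembleResults:
    """Fitted ensemble: pooled topics, consensus partition, diagnostics."""

    def __init__(self, model: TopicEnsembleModel, pool: TopicPool, consensus: ConsensusResult):
        self.model = model
        self.pool = pool
        self.consensus = consensus

    @property
    def assignment(self) -> np.ndarray:
        return self.consensus.assignment

    @property
    def doc_scores(self) -> np.ndarray:
        return self.consensus.doc_scores

    @property
    def doc_ids(self) -> tuple[str, ...]:
        return self.consensus.doc_ids

    def evaluate(self, labels):
        """Match clusters to binary labels and compute the metrics report."""
        from .evaluation import compute_metrics, match_clusters_to_labels

        cm, mapping = match_clusters_to_labels(self.assignment, labels)
        return compute_metrics(cm, mapping)

    def keyword_table(self, n_terms: int = 10, run: int = 0):
        """Per-cluster, per-topic keyword lists from one representative run.

        Returns ``{cluster: [(topic_index, [terms...]), ...]}`` using the
        requested run's topics grouped by their consensus cluster.
        """
        k = self.model.config.n_topics
        vocab = self.pool.vocabulary
        table: dict[int, list] = {}
        for j in range(k):
            row = run * k + j
            cluster = int(self.consensus.topic_cluster[row])
            words = top_keywords(self.pool.topics[row], vocab, n_terms)
            table.setdefault(cluster, []).append((j, words))
        return table

    def document_distances(self) -> np.ndarray:
        from .visualization import document_distance_matrix

        return document_distance_matrix(self.consensus)

    def mds(self):
        from .visualization import mds_embed

        return mds_embed(self.document_distances())

    def summary(self) -> str:
        cfg = self.model.config
        sizes = self.consensus.cluster_sizes()
        lines = [
            "Topic ensemble consensus clustering",
            "===================================",
            f"Documents:          {len(self.doc_ids)}",
            f"Vocabulary (terms): {len(self.pool.vocabulary)}",
            f"Ensemble members:   {self.pool.n_members} "
            f"({cfg.n_seeds} runs x {cfg.n_topics} topics)",
            f"Consensus clusters: {cfg.n_clusters}",
            "Cluster sizes:      "
            + ", ".join(f"cluster {c}: {s} docs" for c, s in enumerate(sizes)),
        ]
        table = self.keyword_table(n_terms=5)
        for cluster in sorted(table):
            lines.append(f"Top terms, cluster {cluster} (run 0 topics):")
            for j, words in table[cluster]:
                lines.append(f"  topic {j}: " + " ".join(words))
        return "\n".join(lines)
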