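"""Synthetic labeled corpora with the structure the pipeline assumes.

Two respondent groups share a background vocabulary but differ in the
topic words they use; singleton rare words are injected so that both
vocabulary-pruning rules have something to remove.  Each document draws
tokens independently: a background word with probability ``p_background``
(uniform over the background vocabulary), a topic word with probability
``p_group`` and a rare word with probability ``p_rare``.

Two structural points matter:

* Topic words are drawn from a small per-document subset (default 8) of
  the group's 40-word vocabulary rather than the whole of it.  Each
  respondent dwelling on a handful of personal themes is what makes
  discriminative words concentrated in a minority of documents — exactly
  the profile the max/total ratio rule is designed to *keep*, while
  evenly-spread background words are removed by it.
* ``separation`` in [0, 1] scales how exclusive topic words are: the
  probability that a topic-word draw uses the document's own group
  vocabulary is ``0.5 + separation / 2``, so 1.0 gives fully exclusive
  groups and 0.0 one shared word distribution (clustering at chance).

Rare words are singletons: each is used at most once corpus-wide and
then retired; once exhausted, rare draws fall back to background words.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .corpus import Corpus, Document
from .features import (
    FilterThresholds,
    build_term_document_matrix,
    compute_tfidf,
    filter_terms,
)

__all__ = [
    "GeneratorConfig",
    "WordRoles",
    "generate_corpus",
    "ground_truth_filter_expectations",
]


@dataclass(frozen=True)
class GeneratorConfig:
    n_per_group: int = 50
    doc_length: int = 200
    n_background: int = 60
    n_group_words: int = 40  # per group
    n_rare: int = 30
    p_background: float = 0.5
    p_group: float = 0.45
    p_rare: float = 0.05
    separation: float = 1.0
    n_group_words_per_doc: int = 8
    zipf_exponent: float = 0.0  # 0 = uniform within each role vocabulary
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = (
            self.n_per_group, self.doc_length, self.n_background,
            self.n_group_words, self.n_rare,
        )
        if any(s < 0 for s in sizes):
            raise ValueError("sizes must be >= 0")
        probs = (self.p_background, self.p_group, self.p_rare)
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("mixing weights must be >= 0 and sum to 1")
        if not 0 <= self.separation <= 1:
            raise ValueError("separation must be in [0, 1]")
        if not 1 <= self.n_group_words_per_doc <= max(self.n_group_words, 1):
            raise ValueError("n_group_words_per_doc must be in [1, n_group_words]")


@dataclass(frozen=True)
class WordRoles:
    """Ground-truth role of every vocabulary word, for test assertions."""

    background: tuple[str, ...]
    group0: tuple[str, ...]
    group1: tuple[str, ...]
    rare: tuple[str, ...]

    def role_of(self, word: str) -> str:
        for role in ("background", "group0", "group1", "rare"):
            if word in getattr(self, role):
                return role
        raise KeyError(word)


def _role_weights(n: int, exponent: float) -> np.ndarray:
    if exponent <= 0:
        return np.full(n, 1.0 / n)
    w = 1.0 / np.arange(1, n + 1) ** exponent
    return w / w.sum()


def generate_corpus(config: GeneratorConfig = GeneratorConfig()):
    """Draw a labeled two-group corpus; returns ``(Corpus, WordRoles)``.

    Deterministic for a fixed ``config.seed``; labels are 0 for group 0
    and 1 for group 1, balanced by construction.
    """
    rng = np.random.default_rng(config.seed)
    background = tuple(f"bg_{i:03d}" for i in range(config.n_background))
    group_vocab = (
        tuple(f"g0_{i:03d}" for i in range(config.n_group_words)),
        tuple(f"g1_{i:03d}" for i in range(config.n_group_words)),
    )
    rare = tuple(f"rare_{i:03d}" for i in range(config.n_rare))
    rare_left = list(range(config.n_rare))
    bg_w = _role_weights(config.n_background, config.zipf_exponent)
    sub_w = _role_weights(config.n_group_words_per_doc, config.zipf_exponent)
    p_own = config.p_group * (0.5 + config.separation / 2.0)
    rare_exhausted_warned = False

    documents: list[Document] = []
    for group in (0, 1):
        for d in range(config.n_per_group):
            own = rng.choice(
                config.n_group_words, size=config.n_group_words_per_doc, replace=False
            )
            other = rng.choice(
                config.n_group_words, size=config.n_group_words_per_doc, replace=False
            )
            tokens: list[str] = []
            for _ in range(config.doc_length):
                u = rng.random()
                if u < config.p_background:
                    tokens.append(background[rng.choice(config.n_background, p=bg_w)])
                elif u < config.p_background + p_own:
                    tokens.append(
                        group_vocab[group][own[rng.choice(len(own), p=sub_w)]]
                    )
                elif u < config.p_background + config.p_group:
                    tokens.append(
                        group_vocab[1 - group][other[rng.choice(len(other), p=sub_w)]]
                    )
                else:
                    if rare_left:
                        tokens.append(rare[rare_left.pop(0)])
                    else:
                        if not rare_exhausted_warned:
                            warnings.warn(
                                "rare vocabulary exhausted; falling back to background words"
                            )
                            rare_exhausted_warned = True
                        tokens.append(background[rng.choice(config.n_background, p=bg_w)])
            documents.append(
                Document(
                    id=f"doc_{group * config.n_per_group + d:03d}",
                    raw_text=" ".join(tokens),
                    tokens=tuple(tokens),
                    label=group,
                )
            )
    roles = WordRoles(background, group_vocab[0], group_vocab[1], rare)
    corpus = Corpus(documents, {"generator_seed": config.seed})
    return corpus, roles


def ground_truth_filter_expectations(
    corpus: Corpus,
    roles: WordRoles,
    thresholds: FilterThresholds = FilterThresholds(),
) -> dict:
    """Per-role outcome fractions of the two filter rules on a generated corpus.

    Returns, for each word role that actually occurs in the corpus, the
    fraction of its words removed as rare (rule i), removed as common
    (rule ii) and retained — for assertion in tests.
    """
    tfidf = compute_tfidf(build_term_document_matrix(corpus))
    result = filter_terms(tfidf, thresholds)
    kept = set(result.tfidf.vocabulary)
    report: dict[str, dict[str, float]] = {}
    for role in ("background", "group0", "group1", "rare"):
        words = [w for w in getattr(roles, role) if w in tfidf.vocabulary]
        if not words:
            continue
        n = len(words)
        report[role] = {
            "removed_rare": sum(result.discarded.get(w) == "rare" for w in words) / n,
            "removed_common": sum(result.discarded.get(w) == "common" for w in words) / n,
            "retained": sum(w in kept for w in words) / n,
            "n_words": n,
        }
    return report
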