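"""Corpus ingestion, tokenization and result serialization.

A corpus holds one document per respondent (all of a respondent's answers
concatenated).  Tokenization is pluggable: a segmenter callable maps raw
text to a token sequence, and a :class:`TokenizerSpec` bundles it with a
stopword list and the cleanup flags.  The default segmenter splits on
whitespace and falls back to single characters for CJK runs, so the
package works without any language-specific dependency; a proper Cantonese
segmenter (e.g. PyCantonese's) can be injected by the caller.
"""

from __future__ import annotations

import csv
import json
import unicodedata
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence

__all__ = [
    "Document",
    "Corpus",
    "TokenizerSpec",
    "default_segmenter",
    "load_stopwords",
    "normalize_token",
    "preprocess",
    "preprocess_corpus",
    "read_corpus",
    "write_results",
]


def _is_cjk(ch: str) -> bool:
    cp = ord(ch)
    return (
        0x4E00 <= cp <= 0x9FFF
        or 0x3400 <= cp <= 0x4DBF
        or 0xF900 <= cp <= 0xFAFF
        or 0x20000 <= cp <= 0x2FA1F
    )


def default_segmenter(text: str) -> list[str]:
    """Whitespace tokenizer with a per-character fallback for CJK runs.

    Unsegmented CJK text carries no word boundaries, so without a real
    segmenter each CJK character becomes its own token; ASCII/other runs
    between CJK characters stay whole.
    """
    tokens: list[str] = []
    for chunk in text.split():
        buf = ""
        for ch in chunk:
            if _is_cjk(ch):
                if buf:
                    tokens.append(buf)
                    buf = ""
                tokens.append(ch)
            else:
                buf += ch
        if buf:
            tokens.append(buf)
    return tokens


def normalize_token(token: str) -> str:
    """NFC-normalize; lowercase ASCII letters only (CJK has no case)."""
    t = unicodedata.normalize("NFC", token)
    return "".join(c.lower() if c.isascii() else c for c in t)


_FULLWIDTH_DIGITS = set("０１２３４５６７８９")


def _is_numeric(token: str) -> bool:
    return bool(token) and all(c.isascii() and c.isdigit() or c in _FULLWIDTH_DIGITS for c in token)


def _is_punctuation(token: str) -> bool:
    return bool(token) and all(unicodedata.category(c)[0] in "PS" for c in token)


@dataclass(frozen=True)
class Document:
    """One respondent's transcript with optional binary stress label.

    ``label`` is 0 for low stress and 1 for high stress (derived externally,
    e.g. from a burden-inventory cutoff); ``tokens`` is empty until
    :func:`preprocess` runs.
    """

    id: str
    raw_text: str
    tokens: tuple[str, ...] = ()
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("document id must be nonempty")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass
class Corpus:
    documents: list[Document]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for doc in self.documents:
            if doc.id in seen:
                raise ValueError(f"duplicate document id: {doc.id!r}")
            seen.add(doc.id)
        labelled = [d for d in self.documents if d.label is not None]
        if labelled and len(labelled) != len(self.documents):
            missing = next(d.id for d in self.documents if d.label is None)
            raise ValueError(
                f"labels must be all-or-none; document {missing!r} has no label"
            )

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(d.id for d in self.documents)

    @property
    def labels(self) -> Optional[tuple[int, ...]]:
        if not self.documents or self.documents[0].label is None:
            return None
        return tuple(d.label for d in self.documents)


@dataclass(frozen=True)
class TokenizerSpec:
    """Segmenter + cleanup rules applied by :func:`preprocess`.

    The stopword set is normalized with the same rule as tokens so that
    matching is deterministic.
    """

    name: str = "default"
    segmenter: Callable[[str], Sequence[str]] = default_segmenter
    stopwords: frozenset[str] = frozenset()
    drop_numeric: bool = True
    drop_punctuation: bool = True

    def __post_init__(self) -> None:
        normalized = frozenset(normalize_token(w) for w in self.stopwords)
        object.__setattr__(self, "stopwords", normalized)


def load_stopwords(path: str | Path) -> frozenset[str]:
    """Read a stopword list: one token per line, ``#`` starts a comment."""
    words = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            words.append(normalize_token(line))
    return frozenset(words)


def preprocess(doc: Document, spec: TokenizerSpec = TokenizerSpec()) -> Document:
    """Segment ``raw_text`` and drop stopword / numeric / punctuation tokens."""
    try:
        raw_tokens = spec.segmenter(doc.raw_text)
    except Exception as exc:  # pragma: no cover - segmenter is user code
        raise RuntimeError(f"segmenter failed on document {doc.id!r}: {exc}") from exc
    kept = []
    for tok in raw_tokens:
        tok = normalize_token(tok).strip()
        if not tok:
            continue
        if tok in spec.stopwords:
            continue
        if spec.drop_numeric and _is_numeric(tok):
            continue
        if spec.drop_punctuation and _is_punctuation(tok):
            continue
        kept.append(tok)
    return replace(doc, tokens=tuple(kept))


def preprocess_corpus(corpus: Corpus, spec: TokenizerSpec = TokenizerSpec()) -> Corpus:
    docs = [preprocess(d, spec) for d in corpus.documents]
    meta = dict(corpus.metadata)
    meta["tokenizer"] = spec.name
    return Corpus(docs, meta)


def _coerce_label(value) -> Optional[int]:
    if value is None or value == "":
        return None
    return int(value)


def read_corpus(path: str | Path, format: str) -> Corpus:
    """Load a corpus from ``jsonl``, ``csv`` or a ``txt-dir`` directory.

    JSONL rows and CSV rows carry ``id`` and ``text`` fields plus an
    optional binary ``label``; for a directory of ``.txt`` files the
    filename stem is the id and files are read in sorted order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    docs: list[Document] = []
    if format == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                row = json.loads(line)
                if "id" not in row or "text" not in row:
                    raise ValueError(f"jsonl line {lineno}: missing id or text field")
                docs.append(
                    Document(str(row["id"]), row["text"], label=_coerce_label(row.get("label")))
                )
    elif format == "csv":
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            for rowno, row in enumerate(reader, start=2):
                if row.get("id") is None or row.get("text") is None:
                    raise ValueError(f"csv row {rowno}: missing id or text field")
                docs.append(
                    Document(str(row["id"]), row["text"], label=_coerce_label(row.get("label")))
                )
    elif format == "txt-dir":
        for f in sorted(path.glob("*.txt")):
            docs.append(Document(f.stem, f.read_text(encoding="utf-8")))
    else:
        raise ValueError(f"unknown corpus format: {format!r}")
    return Corpus(docs, {"source": str(path), "format": format})


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Serialize a corpus to JSONL (tokens joined by spaces into ``text``)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for doc in corpus.documents:
            row: dict = {"id": doc.id, "text": doc.raw_text}
            if doc.label is not None:
                row["label"] = doc.label
            fh.write(json.dumps(row, ensure_ascii=False) + "\n")


def write_results(consensus, metrics, path: str | Path) -> list[Path]:
    """Write per-document assignments (CSV) and, if given, a metrics JSON.

    ``consensus`` must carry ``doc_ids``, ``assignment`` and ``doc_scores``.
    Output is byte-stable for identical inputs.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written = []
    n_clusters = consensus.doc_scores.shape[1]
    assign_path = path / "assignments.csv"
    with assign_path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["id", "cluster"] + [f"score_cluster{c}" for c in range(n_clusters)])
        for i, doc_id in enumerate(consensus.doc_ids):
            scores = [f"{consensus.doc_scores[i, c]:.10g}" for c in range(n_clusters)]
            writer.writerow([doc_id, int(consensus.assignment[i])] + scores)
    written.append(assign_path)
    if metrics is not None:
        metrics_path = path / "metrics.json"
        metrics_path.write_text(
            json.dumps(metrics.to_dict(), indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        written.append(metrics_path)
    return written
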