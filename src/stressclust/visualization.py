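"""Diagnostic outputs: consensus-profile distances, classical MDS, renders.

MDS is run on cosine distances between the per-document consensus score
profiles (how strongly each document loads on each topic cluster); the
classical Torgerson variant is used because it is deterministic — an
eigendecomposition of the double-centered squared-distance matrix, no
iterative stress minimization.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .ensemble import ConsensusResult

__all__ = [
    "Embedding2D",
    "document_distance_matrix",
    "mds_embed",
    "render_outputs",
]


def document_distance_matrix(consensus: ConsensusResult) -> np.ndarray:
    """Pairwise cosine distances between document consensus profiles."""
    scores = np.asarray(consensus.doc_scores, dtype=float)
    norms = np.linalg.norm(scores, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValueError(
            f"document {consensus.doc_ids[zero[0]]!r} has an all-zero score profile"
        )
    unit = scores / norms[:, None]
    D = 1.0 - unit @ unit.T
    D = np.clip(D, 0.0, None)
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return D


@dataclass(frozen=True)
class Embedding2D:
    coordinates: np.ndarray  # n x 2, column means ~ 0
    eigenvalues: np.ndarray  # the two retained eigenvalues
    stress: float  # relative residual of the embedded distances


def mds_embed(D: np.ndarray) -> Embedding2D:
    """Classical (Torgerson) MDS of a distance matrix into the plane.

    Double-centers ``-D**2 / 2``, keeps the top-2 eigenpairs, and fixes
    the sign of each axis so its largest-magnitude coordinate is
    positive.  If fewer than two positive eigenvalues exist the second
    axis is zero-filled (with a warning).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or n < 2:
        raise ValueError("D must be a square distance matrix with n >= 2")
    if not np.allclose(D, D.T, atol=1e-9) or not np.allclose(np.diag(D), 0, atol=1e-9):
        raise ValueError("D must be symmetric with a zero diagonal")
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (D**2) @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    n_pos = int((eigvals[:2] > 1e-12).sum())
    if n_pos < 2:
        warnings.warn("fewer than 2 positive eigenvalues; embedding padded to 2-d")
    coords = np.zeros((n, 2))
    for axis in range(n_pos):
        coords[:, axis] = eigvecs[:, axis] * np.sqrt(eigvals[axis])
    for axis in range(2):
        col = coords[:, axis]
        if col.any() and col[np.argmax(np.abs(col))] < 0:
            coords[:, axis] = -col
    embedded = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    denom = np.sqrt((D**2).sum())
    stress = float(np.sqrt(((D - embedded) ** 2).sum()) / denom) if denom > 0 else 0.0
    return Embedding2D(coords, eigvals[:2].copy(), stress)


def _write_keyword_csv(path: Path, rows) -> None:
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["topic", "rank", "term"])
        writer.writerows(rows)


def render_outputs(
    embedding: Embedding2D,
    consensus: ConsensusResult,
    keyword_tables: dict,
    path: str | Path,
    image_format: str = "png",
) -> list[Path]:
    """Write the MDS scatter, a cluster-membership diagram and keyword CSVs.

    ``keyword_tables`` maps cluster id to ``[(topic_index, [terms...]), ...]``
    (see ``TopicEnsembleResults.keyword_table``).  CSV bytes are
    deterministic for identical inputs.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    coords = embedding.coordinates
    assignment = consensus.assignment
    if coords.shape[0] != len(assignment):
        raise ValueError("embedding and consensus document counts differ")
    written: list[Path] = []

    scatter_path = path / f"mds_scatter.{image_format}"
    fig, ax = plt.subplots(figsize=(6, 5))
    markers = ["^", "v", "o", "s"]
    for c in range(consensus.doc_scores.shape[1]):
        mask = assignment == c
        ax.scatter(
            coords[mask, 0], coords[mask, 1],
            marker=markers[c % len(markers)], label=f"cluster {c}", alpha=0.8,
        )
    centroids = np.array(
        [coords[assignment == c].mean(axis=0)
         for c in range(consensus.doc_scores.shape[1])
         if (assignment == c).any()]
    )
    if len(centroids) == 2:
        # discriminative direction: segment between the cluster centroids
        ax.annotate(
            "", xy=tuple(centroids[1]), xytext=tuple(centroids[0]),
            arrowprops=dict(color="red", arrowstyle="->", lw=2),
        )
    ax.set_xlabel("MDS axis 1")
    ax.set_ylabel("MDS axis 2")
    ax.legend()
    fig.tight_layout()
    fig.savefig(scatter_path)
    plt.close(fig)
    written.append(scatter_path)

    diagram_path = path / f"cluster_membership.{image_format}"
    fig, ax = plt.subplots(figsize=(6, 5))
    n_clusters = consensus.doc_scores.shape[1]
    rng_angles = np.linspace(0, 2 * np.pi, max(len(assignment), 1), endpoint=False)
    centers = np.array(
        [[np.cos(2 * np.pi * c / n_clusters), np.sin(2 * np.pi * c / n_clusters)]
         for c in range(n_clusters)]
    ) * 2.0
    for i, (doc_id, c) in enumerate(zip(consensus.doc_ids, assignment)):
        cx, cy = centers[int(c)]
        x = cx + 0.8 * np.cos(rng_angles[i])
        y = cy + 0.8 * np.sin(rng_angles[i])
        ax.text(x, y, doc_id, fontsize=5, ha="center", va="center")
    for c, (cx, cy) in enumerate(centers):
        ax.add_patch(plt.Circle((cx, cy), 1.0, fill=False))
        ax.text(cx, cy + 1.1, f"cluster {c}", ha="center", fontsize=10)
    ax.set_xlim(-3.5, 3.5)
    ax.set_ylim(-3.5, 3.5)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(diagram_path)
    plt.close(fig)
    written.append(diagram_path)

    for cluster in sorted(keyword_tables):
        rows = [
            (topic, rank + 1, term)
            for topic, terms in keyword_tables[cluster]
            for rank, term in enumerate(terms)
        ]
        csv_path = path / f"keywords_cluster{cluster}.csv"
        _write_keyword_csv(csv_path, rows)
        written.append(csv_path)
    return written
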