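"""Sentence-level word co-occurrence via Spearman rank correlation.

The unit of co-occurrence is the sentence: an occurrence matrix of
sentences x vocabulary holds per-sentence term counts (or presence with
``binary=True``), and Spearman's rank correlation is computed between all
possible pairs of word columns across sentences. Word pairs with a
coefficient of at least ``rho_min`` (default 0.1) are retained as the edges
of the word network; the rule is one-sided, so negatively associated pairs
are never retained at the default.

For 0/1 occurrence vectors the Spearman coefficient coincides with the
Pearson (phi) coefficient of the raw vectors, because the average-tie rank
transform of a binary vector is affine.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import rankdata

from .preprocess import Corpus

logger = logging.getLogger(__name__)

__all__ = [
    "OccurrenceMatrix",
    "EdgeCandidate",
    "EdgeList",
    "build_occurrence_matrix",
    "spearman_pair",
    "pairwise_cooccurrence",
    "threshold_edges",
    "write_edge_list",
    "read_edge_list",
    "write_occurrence_matrix",
]

#: Absolute slack when comparing a coefficient against the retention
#: threshold, so a pair whose exact coefficient equals rho_min is retained
#: despite floating-point representation of the threshold.
RHO_EPS = 1e-9


@dataclass
class OccurrenceMatrix:
    """Sentences x vocabulary matrix of per-sentence term occurrence.

    ``vocabulary`` is sorted lexicographically; ``sentence_index`` holds
    (respondent_id, sentence ordinal) per row. Values are counts, or 0/1
    presence when built with ``binary=True``.
    """

    vocabulary: list[str]
    sentence_index: list[tuple[str, int]]
    values: np.ndarray  # shape (n_sentences, n_vocab), integer counts

    @property
    def n_sentences(self) -> int:
        return self.values.shape[0]

    @property
    def n_vocab(self) -> int:
        return self.values.shape[1]

    def column(self, lemma: str) -> np.ndarray:
        return self.values[:, self.vocabulary.index(lemma)]


@dataclass(frozen=True)
class EdgeCandidate:
    word_a: str
    word_b: str
    rho: float

    def __post_init__(self) -> None:
        if self.word_a >= self.word_b:
            raise ValueError("edge endpoints must satisfy word_a < word_b")


@dataclass
class EdgeList:
    edges: list[EdgeCandidate]
    rho_min: float
    n_sentences: int

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(self.edges)


def build_occurrence_matrix(
    corpus: Corpus, min_sentence_freq: int = 5, binary: bool = False
) -> OccurrenceMatrix:
    """Count lemma occurrences per non-empty clean sentence.

    Lemmas occurring in fewer than ``min_sentence_freq`` sentences are
    removed (applied once, not iteratively); sentences are kept even if the
    removal empties them, so the sentence set does not depend on the
    frequency cut.
    """
    if min_sentence_freq < 1:
        raise ValueError("min_sentence_freq must be >= 1")
    sentences = corpus.clean_sentences()
    if not sentences:
        raise ValueError("no sentences: corpus is empty after preprocessing")

    support: dict[str, int] = {}
    for _, _, sent in sentences:
        for lemma in set(sent.tokens):
            support[lemma] = support.get(lemma, 0) + 1
    vocabulary = sorted(w for w, c in support.items() if c >= min_sentence_freq)
    if not vocabulary:
        raise ValueError(
            f"no lemma reaches min_sentence_freq={min_sentence_freq}"
        )
    col = {w: j for j, w in enumerate(vocabulary)}

    values = np.zeros((len(sentences), len(vocabulary)), dtype=np.int64)
    index = []
    for i, (rid, ordinal, sent) in enumerate(sentences):
        index.append((rid, ordinal))
        for lemma in sent.tokens:
            j = col.get(lemma)
            if j is not None:
                values[i, j] += 1
    if binary:
        values = (values > 0).astype(np.int64)
    return OccurrenceMatrix(vocabulary, index, values)


def spearman_pair(x: np.ndarray, y: np.ndarray) -> float | None:
    """Spearman's rank correlation of two occurrence vectors.

    Computed as the Pearson correlation of average-tie ranks. Returns None
    (undefined) when either vector is constant, so an undefined coefficient
    can never silently enter the edge list.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 1 or x.size < 2:
        raise ValueError("vectors must be 1-D with length >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return None
    rx = rankdata(x)  # average ranks for ties
    ry = rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def pairwise_cooccurrence(matrix: OccurrenceMatrix) -> list[EdgeCandidate]:
    """Spearman coefficients for all pairs of non-constant word columns.

    Columns are rank-transformed once and correlated via a single matrix
    product, which is exactly the pairwise Spearman computation. Constant
    columns (including all-zero columns left by the frequency cut) produce
    no candidates and are logged.
    """
    if matrix.n_vocab < 2:
        raise ValueError("need at least 2 vocabulary columns")
    values = matrix.values
    constant = np.all(values == values[0, :], axis=0)
    if constant.any():
        dropped = [w for w, c in zip(matrix.vocabulary, constant) if c]
        logger.info(
            "dropping %d constant column(s) with undefined correlation: %s",
            len(dropped), ", ".join(dropped[:10]),
        )
    keep = ~constant
    words = [w for w, k in zip(matrix.vocabulary, keep) if k]
    if len(words) < 2:
        return []
    ranks = rankdata(values[:, keep], axis=0).astype(float)
    ranks -= ranks.mean(axis=0)
    norms = np.sqrt(np.einsum("ij,ij->j", ranks, ranks))
    corr = (ranks.T @ ranks) / np.outer(norms, norms)
    candidates = []
    for a in range(len(words)):
        for b in range(a + 1, len(words)):
            wa, wb = sorted((words[a], words[b]))
            candidates.append(EdgeCandidate(wa, wb, float(corr[a, b])))
    return candidates


def threshold_edges(
    candidates: list[EdgeCandidate],
    rho_min: float = 0.1,
    n_sentences: int = 0,
) -> EdgeList:
    """Retain candidates with rho >= rho_min ("at least" is inclusive).

    One-sided and signed: negative coefficients are never retained at the
    default threshold. Output order is deterministic (word_a, word_b).
    """
    if not (-1.0 < rho_min <= 1.0):
        raise ValueError(f"rho_min must be in (-1, 1], got {rho_min}")
    kept = [c for c in candidates if c.rho >= rho_min - RHO_EPS]
    kept.sort(key=lambda c: (c.word_a, c.word_b))
    return EdgeList(kept, rho_min=rho_min, n_sentences=n_sentences)


# --------------------------------------------------------------------------
# I/O


def write_edge_list(edge_list: EdgeList, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["word_a", "word_b", "rho"])
        for e in edge_list:
            writer.writerow([e.word_a, e.word_b, repr(e.rho)])


def read_edge_list(
    path: str | Path, rho_min: float = 0.1, n_sentences: int = 0
) -> EdgeList:
    edges = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            edges.append(
                EdgeCandidate(row["word_a"], row["word_b"], float(row["rho"]))
            )
    return EdgeList(edges, rho_min=rho_min, n_sentences=n_sentences)


def write_occurrence_matrix(matrix: OccurrenceMatrix, out_dir: str | Path) -> None:
    """Sparse triplet export (MatrixMarket) with vocabulary and
    sentence-index sidecar CSVs."""
    from scipy import sparse
    from scipy.io import mmwrite

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mmwrite(out_dir / "occurrence.mtx", sparse.coo_matrix(matrix.values))
    with open(out_dir / "vocabulary.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["column", "lemma"])
        for j, w in enumerate(matrix.vocabulary):
            writer.writerow([j, w])
    with open(out_dir / "sentences.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["row", "respondent_id", "sentence_ordinal"])
        for i, (rid, k) in enumerate(matrix.sentence_index):
            writer.writerow([i, rid, k])
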