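"""Word-context matrices, weighting schemes, and SVD-smoothed spaces.

The pipeline is: raw count matrix (documents or window-2 co-occurring
words as contexts) -> optional tf-idf (log-entropy) or ppmi weighting ->
optional truncated-SVD smoothing -> cosine similarity between word rows.
Natural logarithms are used throughout; the entropy term is normalized by
``log(n_c)`` so the base cancels there, and any fixed base elsewhere only
rescales rows, leaving cosines unchanged.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite
from scipy.sparse.linalg import svds

from .corpusio import Corpus

logger = logging.getLogger(__name__)

CONTEXT_TYPES = ("document", "word")
WEIGHTINGS = ("raw", "tfidf", "ppmi")


@dataclass
class WordContextMatrix:
    """Sparse counts or weights of target words over contexts."""

    matrix: sp.csr_matrix
    row_labels: list[str]
    col_labels: list[str]
    context_type: str
    weighting: str = "raw"

    def __post_init__(self):
        if self.matrix.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("matrix shape does not match label lengths")
        if self.context_type not in CONTEXT_TYPES:
            raise ValueError(f"context_type must be one of {CONTEXT_TYPES}")
        if self.weighting not in WEIGHTINGS:
            raise ValueError(f"weighting must be one of {WEIGHTINGS}")
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValueError("matrix values must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def sparsity(self) -> float:
        """Fraction of zero elements."""
        n_w, n_c = self.matrix.shape
        return 1.0 - self.matrix.nnz / (n_w * n_c)

    def row(self, word: str) -> np.ndarray:
        return np.asarray(self.matrix[self.row_labels.index(word)].todense()).ravel()

    def write(self, path_prefix: str) -> None:
        """Write as Matrix Market plus sidecar ``.rows``/``.cols`` label files."""
        mmwrite(f"{path_prefix}.mtx", self.matrix)
        for ext, labels in ((".rows", self.row_labels), (".cols", self.col_labels)):
            with open(path_prefix + ext, "w", encoding="utf-8") as fh:
                fh.write("\n".join(labels) + "\n")

    @classmethod
    def read(cls, path_prefix: str, context_type: str = "document",
             weighting: str = "raw") -> "WordContextMatrix":
        mat = sp.csr_matrix(mmread(f"{path_prefix}.mtx"))
        labels = []
        for ext in (".rows", ".cols"):
            with open(path_prefix + ext, encoding="utf-8") as fh:
                labels.append([ln.rstrip("\n") for ln in fh if ln.strip()])
        return cls(mat, labels[0], labels[1], context_type, weighting)


@dataclass
class SemanticSpace:
    """Reduced word vectors supporting cosine similarity."""

    row_labels: list[str]
    vectors: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.row_labels):
            raise ValueError("vectors must be an (n_words, n_r) array")
        if not np.any(self.vectors):
            raise ValueError("semantic space must contain at least one nonzero vector")

    @property
    def n_r(self) -> int:
        return self.vectors.shape[1]

    def vector(self, word: str) -> np.ndarray:
        return self.vectors[self.row_labels.index(word)]

    def unit_vectors(self) -> np.ndarray:
        norms = np.linalg.norm(self.vectors, axis=1)
        safe = np.where(norms > 0, norms, 1.0)
        return self.vectors / safe[:, None]


# ---------------------------------------------------------------------------
# Matrix construction


def build_matrix(
    corpus: Corpus,
    targets: Sequence[str],
    context_type: str = "document",
    window: int = 2,
) -> WordContextMatrix:
    """Build a raw word-context count matrix.

    Document mode: ``f[i, j]`` is the number of occurrences of target ``i``
    in document ``j``.  Word mode: ``f[i, j]`` is the number of ordered
    position pairs within ``window`` tokens of each other (inside one
    document) where target ``i`` co-occurs with vocabulary word ``j``; a
    token never co-occurs with itself at its own position, but distinct
    positions of the same type do count, once per direction.
    """
    if not targets:
        raise ValueError("targets must be non-empty")
    if context_type not in CONTEXT_TYPES:
        raise ValueError(f"context_type must be one of {CONTEXT_TYPES}")
    if window < 1:
        raise ValueError("window must be >= 1")
    targets = list(targets)
    row_of = {w: i for i, w in enumerate(targets)}
    missing = [w for w in targets if w not in corpus.vocabulary]
    if missing:
        logger.warning("%d target(s) absent from corpus; keeping zero rows (e.g. %s)",
                       len(missing), missing[:5])

    counts: Counter = Counter()
    if context_type == "document":
        col_labels = [f"d{j}" for j in range(corpus.n_documents)]
        for j, doc in enumerate(corpus.documents):
            for tok in doc:
                i = row_of.get(tok)
                if i is not None:
                    counts[(i, j)] += 1
    else:
        col_labels = sorted(corpus.vocabulary)
        col_of = {w: j for j, w in enumerate(col_labels)}
        for doc in corpus.documents:
            ids = [col_of[t] for t in doc]
            words = doc
            for d in range(1, window + 1):
                for a in range(len(doc) - d):
                    b = a + d
                    i = row_of.get(words[a])
                    if i is not None:
                        counts[(i, ids[b])] += 1
                    i = row_of.get(words[b])
                    if i is not None:
                        counts[(i, ids[a])] += 1

    if counts:
        rows, cols = zip(*counts.keys())
        data = np.fromiter(counts.values(), dtype=float, count=len(counts))
        mat = sp.csr_matrix((data, (rows, cols)),
                            shape=(len(targets), len(col_labels)))
    else:
        mat = sp.csr_matrix((len(targets), len(col_labels)))
    return WordContextMatrix(mat, targets, col_labels, context_type, "raw")


# ---------------------------------------------------------------------------
# Weighting


def weight(matrix: WordContextMatrix, scheme: str) -> WordContextMatrix:
    """Apply tf-idf (log-entropy) or ppmi weighting to a raw count matrix."""
    if scheme not in ("tfidf", "ppmi"):
        raise ValueError("scheme must be 'tfidf' or 'ppmi'")
    if matrix.weighting != "raw":
        raise ValueError(f"matrix is already weighted ({matrix.weighting})")
    f = matrix.matrix.tocsr().astype(float)
    total = f.sum()
    if total == 0:
        raise ValueError("cannot weight a matrix with zero total count")

    if scheme == "tfidf":
        n_c = f.shape[1]
        if n_c < 2:
            raise ValueError("tf-idf entropy term requires at least 2 contexts")
        row_sums = np.asarray(f.sum(axis=1)).ravel()
        # entropy factor g_i = 1 + sum_k P_ik ln P_ik / ln n_c  (0 for uniform rows)
        g = np.zeros(f.shape[0])
        for i in range(f.shape[0]):
            if row_sums[i] == 0:
                continue
            p = f[i].data / row_sums[i]
            g[i] = 1.0 + np.sum(p * np.log(p)) / np.log(n_c)
        out = f.copy()
        out.data = np.log(out.data + 1.0)
        out = sp.diags(g) @ out
    else:  # ppmi
        row_sums = np.asarray(f.sum(axis=1)).ravel()
        col_sums = np.asarray(f.sum(axis=0)).ravel()
        coo = f.tocoo()
        with np.errstate(divide="ignore"):
            pmi = np.log(coo.data * total / (row_sums[coo.row] * col_sums[coo.col]))
        keep = pmi > 0
        out = sp.csr_matrix((pmi[keep], (coo.row[keep], coo.col[keep])), shape=f.shape)

    out.eliminate_zeros()
    # clamp tiny negative round-off from the diagonal scaling
    out.data[out.data < 0] = 0.0
    return WordContextMatrix(out.tocsr(), matrix.row_labels, matrix.col_labels,
                             matrix.context_type, scheme)


# ---------------------------------------------------------------------------
# Smoothing and similarity


def smooth_svd(matrix: WordContextMatrix, n_r: int) -> SemanticSpace:
    """Rank-``n_r`` SVD smoothing; word vectors are rows of ``U_r @ diag(s_r)``.

    With this convention pairwise cosines between word vectors equal the
    cosines between the corresponding rows of the rank-``n_r``
    reconstruction.  If the requested rank exceeds the matrix rank the
    effective dimension is reduced with a warning.
    """
    if n_r < 1:
        raise ValueError("n_r must be >= 1")
    A = matrix.matrix.astype(float)
    n_w, n_c = A.shape
    if n_r > min(n_w, n_c):
        raise ValueError(f"n_r={n_r} exceeds min(n_w, n_c)={min(n_w, n_c)}")
    if A.nnz == 0:
        raise ValueError("cannot smooth an all-zero matrix")

    if n_r < min(n_w, n_c):
        u, s, _ = svds(A, k=n_r)
        order = np.argsort(s)[::-1]
        u, s = u[:, order], s[order]
    else:
        u, s, _ = np.linalg.svd(A.toarray(), full_matrices=False)
        u, s = u[:, :n_r], s[:n_r]

    tol = max(A.shape) * np.finfo(float).eps * (s[0] if len(s) else 0.0)
    rank = int(np.sum(s > tol))
    if rank < n_r:
        logger.warning("requested n_r=%d exceeds matrix rank %d; reducing", n_r, rank)
        u, s = u[:, :rank], s[:rank]
    vectors = u * s
    return SemanticSpace(list(matrix.row_labels), vectors,
                         provenance=f"svd(n_r={vectors.shape[1]}) of "
                                    f"{matrix.context_type}/{matrix.weighting}")


def cosine(space_or_matrix: Union[SemanticSpace, WordContextMatrix],
           w1: str, w2: str) -> float:
    """Cosine similarity between two words; zero vectors give 0 by convention."""
    obj = space_or_matrix
    if isinstance(obj, SemanticSpace):
        labels, get = obj.row_labels, obj.vector
    else:
        labels, get = obj.row_labels, obj.row
    for w in (w1, w2):
        if w not in labels:
            raise KeyError(f"unknown word: {w!r}")
    v1, v2 = np.asarray(get(w1), float), np.asarray(get(w2), float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        logger.info("cosine with zero vector (%r, %r) -> 0", w1, w2)
        return 0.0
    return float(np.dot(v1, v2) / (n1 * n2))


def unit_rows(space_or_matrix: Union[SemanticSpace, WordContextMatrix]) -> tuple[list[str], np.ndarray]:
    """Row labels plus L2-normalized dense row vectors (zero rows stay zero)."""
    obj = space_or_matrix
    if isinstance(obj, SemanticSpace):
        return list(obj.row_labels), obj.unit_vectors()
    dense = np.asarray(obj.matrix.todense(), dtype=float)
    norms = np.linalg.norm(dense, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    return list(obj.row_labels), dense / safe[:, None]
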