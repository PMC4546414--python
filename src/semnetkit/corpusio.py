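"""Corpus and association-norms input, plus a synthetic corpus generator.

The synthetic generator produces text with two kinds of controlled
structure: *paradigmatic clusters* (groups of words drawn into documents
that share a cluster-specific distribution over context words, so cluster
members end up with similar co-occurrence profiles) and *collocation
pairs* (word pairs injected as adjacent bigrams, so they co-occur inside
a two-token window far more often than chance).
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd


class CorpusError(ValueError):
    """Raised for malformed or degenerate corpus/norms input."""


# ---------------------------------------------------------------------------
# Corpus


@dataclass
class Corpus:
    """An ordered collection of tokenized documents."""

    documents: list[list[str]]
    _vocabulary: Optional[Counter] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if len(self.documents) < 1:
            raise CorpusError("corpus must contain at least one document")

    @property
    def vocabulary(self) -> Counter:
        if self._vocabulary is None:
            counts: Counter = Counter()
            for doc in self.documents:
                counts.update(doc)
            self._vocabulary = counts
        return self._vocabulary

    @property
    def n_documents(self) -> int:
        return len(self.documents)

    @property
    def n_tokens(self) -> int:
        return sum(len(d) for d in self.documents)


def read_corpus(path, lowercase: bool = True, min_token_length: int = 1) -> Corpus:
    """Read a plain-text corpus, one whitespace-tokenized document per line."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"corpus file not found: {path}")
    documents = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if lowercase:
                line = line.lower()
            tokens = [t for t in line.split() if len(t) >= min_token_length]
            if tokens:
                documents.append(tokens)
    if not documents:
        raise CorpusError(f"corpus file contains no documents: {path}")
    return Corpus(documents)


def write_corpus(corpus: Corpus, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in corpus.documents:
            fh.write(" ".join(doc) + "\n")


# ---------------------------------------------------------------------------
# Association norms


@dataclass
class AssociationTable:
    """(cue, associate, count) records from a free-association experiment.

    ``count`` is the number of participants who produced the associate for
    the cue; it is preserved so that downstream network construction can
    apply a minimum-count filter.
    """

    records: pd.DataFrame  # columns: cue, associate, count

    def __post_init__(self):
        df = self.records
        for col in ("cue", "associate", "count"):
            if col not in df.columns:
                raise CorpusError(f"association table missing column {col!r}")
        if (df["count"] < 1).any():
            raise CorpusError("association counts must be >= 1")
        if df.duplicated(["cue", "associate"]).any():
            raise CorpusError("duplicate (cue, associate) pairs in association table")

    @property
    def cues(self) -> set:
        return set(self.records["cue"])

    def __len__(self) -> int:
        return len(self.records)


def read_association_norms(
    path,
    cue_col: str = "cue",
    assoc_col: str = "associate",
    count_col: str = "count",
    sep: Optional[str] = None,
    on_duplicate: str = "error",
) -> AssociationTable:
    """Read an association-norms table from CSV/TSV.

    Parameters
    ----------
    sep:
        Field separator; inferred from the file extension when ``None``
        (``.tsv``/``.tab`` -> tab, otherwise comma).
    on_duplicate:
        ``"error"`` (default; norms are expected to be pre-aggregated) or
        ``"sum"`` to merge duplicate (cue, associate) rows by summing counts.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"norms file not found: {path}")
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    for col in (cue_col, assoc_col, count_col):
        if col not in df.columns:
            raise CorpusError(
                f"norms file missing required column {col!r}; found {list(df.columns)}. "
                f"A participant-count column is required (strength alone is not enough)."
            )
    df = df[[cue_col, assoc_col, count_col]].rename(
        columns={cue_col: "cue", assoc_col: "associate", count_col: "count"}
    )
    counts = pd.to_numeric(df["count"], errors="coerce")
    if counts.isna().any() or not np.allclose(counts, counts.round()):
        raise CorpusError("association counts must be integers")
    df["count"] = counts.astype(int)
    if df.duplicated(["cue", "associate"]).any():
        if on_duplicate == "sum":
            df = df.groupby(["cue", "associate"], as_index=False)["count"].sum()
        else:
            raise CorpusError(
                "duplicate (cue, associate) rows; pass on_duplicate='sum' to merge"
            )
    return AssociationTable(df.reset_index(drop=True))


# ---------------------------------------------------------------------------
# Synthetic corpus


@dataclass
class SynthCorpusConfig:
    """Configuration for the synthetic corpus generator."""

    n_clusters: int = 4
    words_per_cluster: int = 5
    n_collocation_pairs: int = 3
    n_documents: int = 200
    doc_length: int = 50
    zipf_exponent: float = 1.0
    seed: Optional[int] = None
    n_context_words: int = 50
    # per-token emission probabilities
    p_member: float = 0.25
    p_collocation: float = 0.08
    # probability mass a cluster devotes to its own context-word subset
    context_boost: float = 0.5

    def __post_init__(self):
        for name in ("n_clusters", "words_per_cluster", "n_collocation_pairs",
                     "n_documents", "doc_length", "n_context_words"):
            if getattr(self, name) < 1:
                raise CorpusError(f"{name} must be >= 1")
        if self.doc_length < 2:
            raise CorpusError("doc_length must be >= 2")
        if self.zipf_exponent < 0:
            raise CorpusError("zipf_exponent must be >= 0")

    @property
    def vocabulary_size(self) -> int:
        return (self.n_clusters * self.words_per_cluster
                + 2 * self.n_collocation_pairs + self.n_context_words)

    def cluster_words(self, c: int) -> list[str]:
        return [f"c{c:02d}w{j:02d}" for j in range(self.words_per_cluster)]

    def collocation_pair(self, i: int) -> tuple[str, str]:
        return f"p{i:02d}a", f"p{i:02d}b"

    def context_words(self) -> list[str]:
        return [f"ctx{r:03d}" for r in range(self.n_context_words)]


def generate_synthetic_corpus(config: SynthCorpusConfig) -> Corpus:
    """Generate a corpus with paradigmatic clusters and syntagmatic pairs.

    Each document samples one cluster; tokens are then drawn independently:
    with probability ``p_collocation`` an adjacent collocation bigram, with
    probability ``p_member`` a member word of the document's cluster, and
    otherwise a context word from the cluster's Zipf-weighted distribution.
    Deterministic for a fixed seed; total token count is exactly
    ``n_documents * doc_length``.
    """
    cfg = config
    if cfg.vocabulary_size > cfg.n_documents * cfg.doc_length:
        raise CorpusError(
            f"vocabulary of {cfg.vocabulary_size} types cannot fit in a token "
            f"budget of {cfg.n_documents * cfg.doc_length}"
        )
    rng = np.random.default_rng(cfg.seed)
    ctx = cfg.context_words()
    n_ctx = len(ctx)
    # global Zipf weights over context words (rank = index)
    ranks = np.arange(1, n_ctx + 1, dtype=float)
    zipf = ranks ** -cfg.zipf_exponent
    # cluster-specific context distributions: a shared Zipf backbone mixed
    # additively with a uniform bump over the cluster's "owned" subset
    # (round-robin ownership).  The additive form keeps the expected
    # aggregate frequency profile monotone in Zipf rank while making the
    # per-cluster distributions distinct.
    owner = np.arange(n_ctx) % cfg.n_clusters
    backbone = zipf / zipf.sum()
    b = cfg.context_boost
    cluster_dists = []
    for c in range(cfg.n_clusters):
        own = (owner == c).astype(float)
        cluster_dists.append((1.0 - b) * backbone + b * own / own.sum())
    members = [cfg.cluster_words(c) for c in range(cfg.n_clusters)]
    pairs = [cfg.collocation_pair(i) for i in range(cfg.n_collocation_pairs)]

    documents = []
    for _ in range(cfg.n_documents):
        c = int(rng.integers(cfg.n_clusters))
        dist = cluster_dists[c]
        doc: list[str] = []
        while len(doc) < cfg.doc_length:
            room = cfg.doc_length - len(doc)
            u = rng.random()
            if u < cfg.p_collocation and room >= 2:
                a, b = pairs[int(rng.integers(len(pairs)))]
                doc.append(a)
                doc.append(b)
            elif u < cfg.p_collocation + cfg.p_member:
                doc.append(members[c][int(rng.integers(cfg.words_per_cluster))])
            else:
                doc.append(ctx[int(rng.choice(n_ctx, p=dist))])
        documents.append(doc)
    return Corpus(documents)
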