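"""Paradigmatic/syntagmatic edge classification against a taxonomy.

An edge is *paradigmatic* when the two words occupy nearby positions in a
supplied is-a hierarchy (shared concept or parent, short superordination
path, or a low common ancestor), and *syntagmatic* otherwise; words not
covered by the taxonomy yield *unknown* and are excluded from the
syntagmatic fraction q.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .network import SemanticNetwork

PARADIGMATIC = "paradigmatic"
SYNTAGMATIC = "syntagmatic"
UNKNOWN = "unknown"


@dataclass
class Taxonomy:
    """Concept DAG (child -> parents) plus a word-to-concept map."""

    parents: dict[str, tuple[str, ...]]
    word_concepts: dict[str, tuple[str, ...]]

    def __post_init__(self):
        g = nx.DiGraph()
        concepts = set(self.parents)
        for child, ps in self.parents.items():
            for p in ps:
                g.add_edge(child, p)
                concepts.add(p)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("taxonomy contains a cycle")
        for word, cs in self.word_concepts.items():
            for c in cs:
                if c not in concepts:
                    raise ValueError(f"word {word!r} maps to unknown concept {c!r}")
        self._concepts = concepts

    def concepts_of(self, word: str) -> tuple[str, ...]:
        return self.word_concepts.get(word, ())

    def ancestors_within(self, concept: str, depth: int) -> dict[str, int]:
        """Map from ancestor concept to its up-distance, including the
        concept itself at distance 0, limited to ``depth`` levels."""
        dist = {concept: 0}
        frontier = [concept]
        for d in range(1, depth + 1):
            nxt = []
            for c in frontier:
                for p in self.parents.get(c, ()):
                    if p not in dist:
                        dist[p] = d
                        nxt.append(p)
            frontier = nxt
        return dist


def read_taxonomy(isa_path, wordmap_path) -> Taxonomy:
    """Read ``child<TAB>parent`` is-a edges and ``word<TAB>concept`` mappings."""
    parents: dict[str, list[str]] = {}
    with open(isa_path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            child, parent = line.split("\t")
            parents.setdefault(child, []).append(parent)
            parents.setdefault(parent, [])
    word_concepts: dict[str, list[str]] = {}
    with open(wordmap_path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            word, concept = line.split("\t")
            word_concepts.setdefault(word, []).append(concept)
    return Taxonomy({k: tuple(v) for k, v in parents.items()},
                    {k: tuple(v) for k, v in word_concepts.items()})


@dataclass
class RelationReport:
    edge_labels: list[tuple[object, object, str]]
    q: float
    n_paradigmatic: int
    n_syntagmatic: int
    n_unknown: int


def classify_edge(tax: Taxonomy, w1: str, w2: str, coord_depth: int = 2) -> str:
    """Classify a word pair as paradigmatic, syntagmatic, or unknown.

    Paradigmatic when any concept pair across the two words (a) is the same
    concept or shares a direct parent, (b) is linked by an is-a path of
    length <= 2 (superordination), or (c) has a common ancestor within
    ``coord_depth`` levels of both (coordination).  Symmetric in its word
    arguments.
    """
    cs1, cs2 = tax.concepts_of(w1), tax.concepts_of(w2)
    if not cs1 or not cs2:
        return UNKNOWN
    for c1, c2 in product(cs1, cs2):
        if c1 == c2:
            return PARADIGMATIC
        up1 = tax.ancestors_within(c1, 2)
        up2 = tax.ancestors_within(c2, 2)
        if c2 in up1 or c1 in up2:          # superordination (child/grandchild)
            return PARADIGMATIC
        if set(tax.parents.get(c1, ())) & set(tax.parents.get(c2, ())):
            return PARADIGMATIC             # shared direct parent
        a1 = tax.ancestors_within(c1, coord_depth)
        a2 = tax.ancestors_within(c2, coord_depth)
        if set(a1) & set(a2):               # low common ancestor (coordination)
            return PARADIGMATIC
    return SYNTAGMATIC


def syntagmatic_fraction(net: SemanticNetwork, tax: Taxonomy,
                         coord_depth: int = 2) -> RelationReport:
    """Classify every edge and compute the syntagmatic fraction q over
    labeled (non-unknown) edges."""
    labels = []
    n_par = n_syn = n_unk = 0
    for u, v in net.edges():
        lab = classify_edge(tax, str(u), str(v), coord_depth=coord_depth)
        labels.append((u, v, lab))
        if lab == PARADIGMATIC:
            n_par += 1
        elif lab == SYNTAGMATIC:
            n_syn += 1
        else:
            n_unk += 1
    labeled = n_par + n_syn
    if labeled == 0:
        raise ValueError("no edge could be labeled against the taxonomy")
    return RelationReport(edge_labels=labels, q=n_syn / labeled,
                          n_paradigmatic=n_par, n_syntagmatic=n_syn,
                          n_unknown=n_unk)


def hierarchy_relation_correlation(pairs: Sequence[tuple[float, float]]) -> float:
    """Pearson correlation between syntagmatic fractions q and the C(k)-k
    log-log correlation coefficients r across a collection of networks."""
    if len(pairs) < 3:
        raise ValueError("need at least 3 (q, r) pairs")
    qs = np.array([p[0] for p in pairs], dtype=float)
    rs = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(qs) == 0 or np.ptp(rs) == 0:
        raise ValueError("correlation undefined for constant input")
    from scipy.stats import pearsonr

    return float(pearsonr(qs, rs)[0])
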