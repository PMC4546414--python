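"""Construction of directed semantic networks.

Three routes are supported: from association norms (cue -> associate edges
filtered by participant count), from a semantic space via the k-nn method
(out-degrees fixed by an external degree sequence), and via the cs-method
(neighbors accumulated in descending cosine order until their cumulative
similarity ratio exceeds a threshold R), with an optional minimum-cosine
cutoff for the thresholded variant.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Union

import numpy as np

from .corpusio import AssociationTable
from .dsm import SemanticSpace, WordContextMatrix, unit_rows
from .network import SemanticNetwork

logger = logging.getLogger(__name__)

Space = Union[SemanticSpace, WordContextMatrix]


def build_association_network(table: AssociationTable, min_count: int = 2,
                              cues: Optional[set] = None) -> SemanticNetwork:
    """Directed network over cue words; edge x->y iff y is itself a cue and
    at least ``min_count`` participants listed y as an associate of x.
    Words appearing only as associates are not represented.  ``cues``
    overrides the node set (default: the table's cue column)."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if len(table) == 0:
        raise ValueError("association table is empty")
    if cues is None:
        cues = table.cues
    df = table.records
    keep = (df["count"] >= min_count) & df["associate"].isin(cues) \
        & (df["cue"] != df["associate"])
    edges = list(df.loc[keep, ["cue", "associate"]].itertuples(index=False, name=None))
    return SemanticNetwork.from_edges(edges, nodes=sorted(cues), directed=True)


def _ranked_neighbors(labels: list[str], sims: np.ndarray, i: int) -> list[int]:
    """Candidate indices for word i sorted by descending cosine, ties broken
    by lexicographically smallest label; excludes self and non-positive cosines."""
    cand = [j for j in range(len(labels)) if j != i and sims[j] > 0]
    cand.sort(key=lambda j: (-sims[j], labels[j]))
    return cand


def knn_network(space: Space, out_degree_seq: Mapping[str, int]) -> SemanticNetwork:
    """Each word gets directed edges to its top-k cosine neighbors, with k
    taken from ``out_degree_seq``; the resulting out-degree sequence equals
    the given one exactly."""
    labels, units = unit_rows(space)
    index = {w: i for i, w in enumerate(labels)}
    n = len(labels)
    for w, k in out_degree_seq.items():
        if w not in index:
            raise KeyError(f"word {w!r} not in space")
        if k < 0:
            raise ValueError("out-degrees must be >= 0")
        if k >= n:
            raise ValueError(f"k={k} for {w!r} must be < vocabulary size {n}")
    edges = []
    for w, k in out_degree_seq.items():
        if k == 0:
            continue
        i = index[w]
        sims = units @ units[i]
        order = np.argsort(-sims, kind="stable")
        # rank by descending cosine with deterministic lexicographic tie-break
        cand = sorted((j for j in order if j != i),
                      key=lambda j: (-sims[j], labels[j]))[:k]
        edges.extend((w, labels[j]) for j in cand)
    return SemanticNetwork.from_edges(edges, nodes=labels, directed=True)


def cs_network(space: Space, R: float, min_cosine: Optional[float] = None) -> SemanticNetwork:
    """Cumulative-similarity network.

    For each word, neighbors are added in descending cosine order until the
    ratio of their summed cosines to the summed positive cosines over all
    other words strictly exceeds ``R``.  Negative cosines are excluded from
    both candidacy and the denominator.  When ``min_cosine`` is given,
    candidates with cosine <= ``min_cosine`` are excluded from the numerator
    and from edge creation, while the denominator keeps all positive
    cosines so that R retains its meaning across filtered runs.
    """
    if not 0 < R < 1:
        raise ValueError("R must be in (0, 1)")
    labels, units = unit_rows(space)
    n = len(labels)
    edges = []
    for i in range(n):
        sims = units @ units[i]
        cand = _ranked_neighbors(labels, sims, i)
        if not cand:
            logger.warning("word %r has no positive cosine; out-degree 0", labels[i])
            continue
        denom = float(sum(sims[j] for j in cand))
        if min_cosine is not None:
            cand = [j for j in cand if sims[j] > min_cosine]
        cum = 0.0
        for j in cand:
            cum += sims[j]
            edges.append((labels[i], labels[j]))
            if cum / denom > R:
                break
    return SemanticNetwork.from_edges(edges, nodes=labels, directed=True)


def cs_out_degrees(space: Space, R: float, min_cosine: Optional[float] = None) -> np.ndarray:
    """Out-degree of every word under the cs rule, without building the graph."""
    if not 0 < R < 1:
        raise ValueError("R must be in (0, 1)")
    labels, units = unit_rows(space)
    n = len(labels)
    degs = np.zeros(n, dtype=int)
    sims_all = units @ units.T
    for i in range(n):
        sims = sims_all[i].copy()
        sims[i] = -np.inf
        pos = sims > 0
        denom = float(sims[pos].sum())
        if denom == 0:
            continue
        vals = np.sort(sims[pos])[::-1]
        if min_cosine is not None:
            vals = vals[vals > min_cosine]
        cum = np.cumsum(vals) / denom
        above = np.flatnonzero(cum > R)
        degs[i] = int(above[0]) + 1 if len(above) else len(vals)
    return degs


def tune_R(space: Space, target_mean_out_degree: float, tolerance: float = 0.1,
           max_iter: int = 60) -> tuple[float, float]:
    """Bisection on R until the cs-method mean out-degree is within
    ``tolerance`` of the target.  Returns ``(R, achieved_mean_out_degree)``."""
    labels, _ = unit_rows(space)
    n = len(labels)
    if target_mean_out_degree < 1:
        raise ValueError("target mean out-degree must be >= 1")
    if target_mean_out_degree > n - 1:
        raise ValueError(f"target {target_mean_out_degree} exceeds n-1={n - 1}")
    lo, hi = 1e-9, 1.0 - 1e-9
    best = None
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        mean_k = float(cs_out_degrees(space, mid).mean())
        if best is None or abs(mean_k - target_mean_out_degree) < abs(best[1] - target_mean_out_degree):
            best = (mid, mean_k)
        if abs(mean_k - target_mean_out_degree) <= tolerance:
            return mid, mean_k
        if mean_k < target_mean_out_degree:
            lo = mid
        else:
            hi = mid
    return best


def undirected_projection(net: SemanticNetwork) -> SemanticNetwork:
    """Replace directed edges with undirected ones (x -- y iff x->y or y->x)."""
    return net.undirected()
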