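"""Growing-network models for semantic network emergence.

The main simulator mixes two attachment mechanisms when a new node joins
with M edges: *differentiation* (an existing host is picked with
probability proportional to its total degree, and the new node connects
to the host plus randomly chosen differentiation-labeled neighbors of the
host) and *correlation* (uniform random existing nodes).  Each edge is
independently oriented toward the existing node with probability gamma.
Also provided: the Barabasi-Albert baseline, the mixed
preferential/random per-edge baseline, and the gamma-tuning loop that
matches the size of the largest strongly connected component to a target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .network import SemanticNetwork

LABEL_NAMES = ("differentiation", "correlation")


@dataclass
class GrowthConfig:
    """Parameters of the growth simulator."""

    n: int
    M: int
    p: float = 0.0          # probability an edge is correlation-labeled
    gamma: float = 1.0      # probability an edge points toward the existing node
    utility: str = "equal"  # "equal" or "log_frequency"
    seed: Optional[int] = None
    frequencies: Optional[dict] = field(default=None, repr=False)

    def __post_init__(self):
        if not self.n > self.M >= 1:
            raise ValueError("require n > M >= 1")
        if not 0 <= self.p <= 1:
            raise ValueError("p must be in [0, 1]")
        if not 0 <= self.gamma <= 1:
            raise ValueError("gamma must be in [0, 1]")
        if self.utility not in ("equal", "log_frequency"):
            raise ValueError("utility must be 'equal' or 'log_frequency'")
        if self.utility == "log_frequency" and self.frequencies is None:
            raise ValueError("log_frequency utility requires a frequency table")


@dataclass
class TuneResult:
    gamma: float
    mean_ncc_by_gamma: dict[float, float]
    chosen_network: SemanticNetwork
    chosen_ncc: int
    reps: int


def expected_edge_count(n: int, M: int) -> int:
    """(n - M) * M new-node edges plus the M(M-1) directed seed-clique edges."""
    return (n - M) * M + M * (M - 1)


# ---------------------------------------------------------------------------
# Core simulator


def _grow_arrays(n: int, M: int, p: float, gamma: float,
                 rng: np.random.Generator, utility: str = "equal",
                 frequencies: Optional[dict] = None,
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate growth; returns (src, dst, label) arrays, label 0 =
    differentiation, 1 = correlation.

    The seed is a fully connected directed clique of M nodes (M(M-1)
    edges, differentiation-labeled).  Each subsequent node contributes
    exactly M distinct edges, so the total edge count is deterministic.
    """
    m_total = expected_edge_count(n, M)
    src = np.empty(m_total, dtype=np.int32)
    dst = np.empty(m_total, dtype=np.int32)
    lab = np.zeros(m_total, dtype=np.int8)
    diff_nbrs: list[list[int]] = [[] for _ in range(n)]
    corr_nbrs: list[list[int]] = [[] for _ in range(n)]
    # one entry per unit of total degree -> uniform index = degree-proportional node
    pool: list[int] = []
    e = 0
    for a in range(M):
        for b in range(M):
            if a != b:
                src[e], dst[e] = a, b
                e += 1
            if b > a:
                diff_nbrs[a].append(b)
                diff_nbrs[b].append(a)
        pool.extend([a] * (2 * (M - 1)))

    if utility == "log_frequency":
        logf = {v: np.log(frequencies.get(v, 0.0) + 1.0) for v in range(n)}

    randint = rng.integers
    for t in range(M, n):
        m_p = M - int(rng.binomial(M, p)) if p > 0 else M
        chosen: set[int] = set()
        order: list[tuple[int, int]] = []   # (target, label)
        if m_p > 0:
            host = pool[int(randint(len(pool)))]
            chosen.add(host)
            order.append((host, 0))
            need = m_p - 1
            cand = diff_nbrs[host]
            if need > 0 and len(cand) >= need:
                if utility == "equal":
                    picked = rng.choice(len(cand), size=need, replace=False)
                else:
                    w = np.array([logf[c] for c in cand])
                    w = w / w.sum() if w.sum() > 0 else None
                    picked = rng.choice(len(cand), size=need, replace=False, p=w)
                for i in picked:
                    order.append((cand[i], 0))
                    chosen.add(cand[i])
                need = 0
            elif need > 0:
                for c in cand:
                    order.append((c, 0))
                    chosen.add(c)
                need -= len(cand)
            # fallback chain: host's correlation neighbors, then uniform
            if need > 0:
                for c in corr_nbrs[host]:
                    if need == 0:
                        break
                    if c not in chosen:
                        order.append((c, 0))
                        chosen.add(c)
                        need -= 1
                while need > 0:
                    c = int(randint(t))
                    if c not in chosen:
                        order.append((c, 0))
                        chosen.add(c)
                        need -= 1
        for _ in range(M - m_p):
            while True:
                c = int(randint(t))
                if c not in chosen:
                    order.append((c, 1))
                    chosen.add(c)
                    break
        toward_old = rng.random(M) < gamma
        for j, (c, label) in enumerate(order):
            if toward_old[j]:
                src[e], dst[e] = t, c
            else:
                src[e], dst[e] = c, t
            lab[e] = label
            e += 1
            if label == 0:
                diff_nbrs[t].append(c)
                diff_nbrs[c].append(t)
            else:
                corr_nbrs[t].append(c)
                corr_nbrs[c].append(t)
            pool.append(t)
            pool.append(c)
    return src, dst, lab


def _to_network(n: int, src: np.ndarray, dst: np.ndarray,
                lab: np.ndarray) -> SemanticNetwork:
    labels = [LABEL_NAMES[x] for x in lab]
    return SemanticNetwork.from_edges(
        zip(src.tolist(), dst.tolist()), nodes=range(n), directed=True,
        labels=labels)


def grow_network(config: GrowthConfig) -> SemanticNetwork:
    """Run the growth simulator and return the labeled directed network."""
    rng = np.random.default_rng(config.seed)
    src, dst, lab = _grow_arrays(config.n, config.M, config.p, config.gamma,
                                 rng, config.utility, config.frequencies)
    return _to_network(config.n, src, dst, lab)


def largest_scc_size(n: int, src: np.ndarray, dst: np.ndarray) -> int:
    adj = sp.csr_matrix((np.ones(len(src), dtype=np.int8), (src, dst)), shape=(n, n))
    _, labels = connected_components(adj, directed=True, connection="strong")
    return int(np.bincount(labels).max())


# ---------------------------------------------------------------------------
# Gamma tuning


def tune_gamma(config: GrowthConfig, target_ncc: int, step: float = 0.005,
               reps: int = 50) -> TuneResult:
    """Scan gamma downward from 1 in steps of ``step``, growing ``reps``
    networks per value, until the mean largest-SCC size passes
    ``target_ncc``; return the gamma whose mean is closest to the target
    and the single replicate (at that gamma) whose size is closest."""
    if not 0 < step < 1:
        raise ValueError("step must be in (0, 1)")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if target_ncc > config.n:
        raise ValueError("target_ncc cannot exceed n")
    rng = np.random.default_rng(config.seed)
    mean_by_gamma: dict[float, float] = {}
    per_gamma_best: dict[float, tuple[int, tuple]] = {}
    gamma = 1.0
    while gamma >= -1e-9:
        gamma = max(gamma, 0.0)
        nccs = []
        best_rep = None
        for _ in range(reps):
            src, dst, lab = _grow_arrays(config.n, config.M, config.p, gamma,
                                         rng, config.utility, config.frequencies)
            ncc = largest_scc_size(config.n, src, dst)
            nccs.append(ncc)
            if best_rep is None or abs(ncc - target_ncc) < abs(best_rep[0] - target_ncc):
                best_rep = (ncc, (src, dst, lab))
        mean_by_gamma[gamma] = float(np.mean(nccs))
        per_gamma_best[gamma] = best_rep
        if mean_by_gamma[gamma] >= target_ncc:
            break
        if gamma == 0.0:
            raise ValueError(
                f"target n_CC={target_ncc} unreachable: mean n_CC at gamma=0 "
                f"is {mean_by_gamma[gamma]:.1f}")
        gamma = round(gamma - step, 10)

    chosen_gamma = min(mean_by_gamma, key=lambda g: abs(mean_by_gamma[g] - target_ncc))
    ncc, (src, dst, lab) = per_gamma_best[chosen_gamma]
    return TuneResult(gamma=chosen_gamma, mean_ncc_by_gamma=mean_by_gamma,
                      chosen_network=_to_network(config.n, src, dst, lab),
                      chosen_ncc=ncc, reps=reps)


# ---------------------------------------------------------------------------
# Baselines


def ba_network(n: int, M: int, seed: Optional[int] = None) -> SemanticNetwork:
    """Undirected Barabasi-Albert preferential-attachment network.

    Starts from an M-node clique; each new node attaches to M distinct
    existing nodes chosen with probability proportional to degree.
    """
    if not n > M >= 1:
        raise ValueError("require n > M >= 1")
    return _pref_random_network(n, M, p_random=0.0, seed=seed)


def liu_network(n: int, M: int, p: float, seed: Optional[int] = None) -> SemanticNetwork:
    """Mixed attachment baseline: each of the M edges of a new node picks
    its target preferentially with probability 1-p or uniformly at random
    with probability p."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    return _pref_random_network(n, M, p_random=p, seed=seed)


def _pref_random_network(n: int, M: int, p_random: float,
                         seed: Optional[int]) -> SemanticNetwork:
    rng = np.random.default_rng(seed)
    edges = []
    pool: list[int] = []
    for a in range(M):
        for b in range(a + 1, M):
            edges.append((a, b))
            pool.append(a)
            pool.append(b)
    randint = rng.integers
    for t in range(M, n):
        chosen: set[int] = set()
        while len(chosen) < M:
            if p_random > 0 and rng.random() < p_random:
                c = int(randint(t))
            else:
                c = pool[int(randint(len(pool)))]
            chosen.add(c)
        for c in chosen:
            edges.append((t, c))
            pool.append(t)
            pool.append(c)
    return SemanticNetwork.from_edges(edges, nodes=range(n), directed=False)


def model_preset(name: str, q: float = 0.0) -> float:
    """Map a model preset to the random-attachment probability p:
    ``A`` -> q, ``B`` -> q/2, ``ST`` -> 0."""
    if not 0 <= q <= 1:
        raise ValueError("q must be in [0, 1]")
    presets = {"A": q, "B": q / 2.0, "ST": 0.0}
    if name not in presets:
        raise ValueError(f"unknown model preset {name!r}; choose from A, B, ST")
    return presets[name]
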