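"""Network descriptors: components, paths, clustering, random baselines,
and the hierarchical scaling of the local clustering coefficient.

Conventions (applied consistently to match published association-network
statistics): the clustering coefficient is the mean of local coefficients
computed on the undirected projection of the analyzed component; directed
path statistics respect edge direction and average over ordered pairs;
the random baseline is a uniform simple graph with the same n and m.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import shortest_path
from scipy.stats import pearsonr

from .network import SemanticNetwork, as_graph


@dataclass
class NetworkStats:
    n: int
    m: int
    n_cc: int
    mean_degree: float
    k_max: int
    diameter: int
    avg_path_length: float
    clustering: float
    l_random: Optional[float] = None
    c_random: Optional[float] = None


@dataclass
class HierarchyStats:
    r: float           # Pearson correlation of (log k, log C(k)) over nodes
    beta: float        # negative slope of log mean-C(k) vs log k
    points: list[tuple[int, float]]  # (degree, mean local clustering)


# ---------------------------------------------------------------------------


def largest_component(net: SemanticNetwork, strong: Optional[bool] = None) -> SemanticNetwork:
    """Induced subgraph on the largest (strongly) connected component.

    ``strong`` defaults to the directedness of the input: strongly connected
    components for directed networks, connected components otherwise.
    """
    g = as_graph(net)
    if g.number_of_nodes() == 0:
        raise ValueError("network is empty")
    if strong is None:
        strong = g.is_directed()
    if g.is_directed() and strong:
        comps = nx.strongly_connected_components(g)
    elif g.is_directed():
        comps = nx.weakly_connected_components(g)
    else:
        comps = nx.connected_components(g)
    # deterministic choice: largest size, ties by smallest sorted node list
    best = max(comps, key=lambda c: (len(c), [str(v) for v in sorted(c, key=str)]))
    return SemanticNetwork(g.subgraph(best).copy())


def local_clustering(net: SemanticNetwork) -> dict:
    """Local clustering coefficient per node, on the undirected projection.

    Nodes with degree < 2 have coefficient 0.
    """
    u = as_graph(net)
    if u.is_directed():
        u = nx.Graph(u)
    return nx.clustering(u)


def clustering(net: SemanticNetwork) -> float:
    """Mean of local clustering coefficients over all nodes."""
    lc = local_clustering(net)
    return float(np.mean(list(lc.values()))) if lc else 0.0


def path_stats(net: SemanticNetwork) -> tuple[float, int]:
    """(average shortest path length, diameter) in hops.

    Directed networks must be strongly connected, undirected ones connected;
    otherwise restrict to the largest component first.
    """
    g = as_graph(net)
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("path statistics require at least 2 nodes")
    nodes = list(g.nodes())
    idx = {v: i for i, v in enumerate(nodes)}
    rows, cols = [], []
    for u, v in g.edges():
        rows.append(idx[u])
        cols.append(idx[v])
    adj = sp.csr_matrix((np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n, n))
    dm = shortest_path(adj, method="D", directed=g.is_directed(), unweighted=True)
    off = ~np.eye(n, dtype=bool)
    d = dm[off]
    if np.isinf(d).any():
        raise ValueError(
            "network is not (strongly) connected; apply largest_component first")
    return float(d.mean()), int(d.max())


def random_baseline(n: int, m: int, directed: bool = False, reps: int = 10,
                    seed: Optional[int] = None) -> tuple[float, float]:
    """Average (L, C) over ``reps`` uniform simple random graphs with exactly
    ``n`` nodes and ``m`` edges.  L is measured on the largest (strongly)
    connected component; C is the mean local coefficient."""
    max_m = n * (n - 1) if directed else n * (n - 1) // 2
    if not 0 <= m <= max_m:
        raise ValueError(f"m={m} infeasible for a simple graph on {n} nodes")
    rng = np.random.default_rng(seed)
    ls, cs = [], []
    for _ in range(reps):
        g = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**32)), directed=directed)
        net = SemanticNetwork(g)
        comp = largest_component(net)
        if comp.n >= 2:
            l, _ = path_stats(comp)
        else:
            l = 0.0
        ls.append(l)
        cs.append(clustering(net))
    return float(np.mean(ls)), float(np.mean(cs))


def hierarchy_fit(net: SemanticNetwork) -> HierarchyStats:
    """Fit the degree scaling of the local clustering coefficient.

    ``r`` is the Pearson correlation of (log k, log C(k)) over nodes with
    k >= 2 and C(k) > 0 (zeros are undefined on a log scale and are
    excluded).  ``beta`` is the negative least-squares slope of
    log(mean C at degree k) against log k over distinct degrees.
    """
    u = as_graph(net)
    if u.is_directed():
        u = nx.Graph(u)
    lc = nx.clustering(u)
    deg = dict(u.degree())
    ks = np.array([deg[v] for v in u if deg[v] >= 2 and lc[v] > 0], dtype=float)
    cs = np.array([lc[v] for v in u if deg[v] >= 2 and lc[v] > 0], dtype=float)
    if len(ks) < 3:
        raise ValueError("need at least 3 nodes with k >= 2 and C(k) > 0")
    r, _ = pearsonr(np.log(ks), np.log(cs))

    by_degree: dict[int, list[float]] = defaultdict(list)
    for v in u:
        if deg[v] >= 2:
            by_degree[deg[v]].append(lc[v])
    points = [(k, float(np.mean(v))) for k, v in sorted(by_degree.items())]
    usable = [(k, c) for k, c in points if c > 0]
    if len(usable) < 3:
        raise ValueError("need at least 3 distinct degrees with positive mean C(k)")
    kk = np.log([k for k, _ in usable])
    cc = np.log([c for _, c in usable])
    slope = np.polyfit(kk, cc, 1)[0]
    return HierarchyStats(r=float(r), beta=float(-slope), points=points)


def summarize(net: SemanticNetwork, reps: int = 10, seed: Optional[int] = None,
              baseline: bool = True) -> NetworkStats:
    """Fill every descriptor used in the summary tables.

    Path statistics are computed on the largest (strongly) connected
    component; the clustering coefficient on the undirected projection of
    that component.  For directed networks the mean degree is m/n and
    ``k_max`` is the maximum in-degree; for undirected ones they are 2m/n
    and the maximum degree.
    """
    g = as_graph(net)
    n, m = g.number_of_nodes(), g.number_of_edges()
    comp = largest_component(net)
    if g.is_directed():
        mean_degree = m / n
        k_max = max(d for _, d in g.in_degree()) if n else 0
    else:
        mean_degree = 2 * m / n
        k_max = max(d for _, d in g.degree()) if n else 0
    if comp.n >= 2:
        l, d = path_stats(comp)
    else:
        l, d = 0.0, 0
    c = clustering(comp)
    l_rand = c_rand = None
    if baseline and m > 0:
        l_rand, c_rand = random_baseline(n, m, directed=g.is_directed(),
                                         reps=reps, seed=seed)
    return NetworkStats(n=n, m=m, n_cc=comp.n, mean_degree=mean_degree,
                        k_max=k_max, diameter=d, avg_path_length=l,
                        clustering=c, l_random=l_rand, c_random=c_rand)
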