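"""Weighted graph-theoretical and homogeneity measures.

Shortest-path computations map each connection weight ``w`` to a length
``1/w`` (stronger connections are shorter), the convention of the standard
weighted complex-network measure suite.  Cube-root formulas (local
efficiency, Onnela clustering) operate on weights rescaled by the graph
maximum, so their values are comparable across graphs.

Measures
--------
- nodal strength: row sums of the weight matrix
- betweenness centrality: fraction of all shortest paths through a node,
  normalized by 1/((n-1)(n-2)) over ordered pairs
- global efficiency: mean inverse shortest-path length over ordered pairs
  (disconnected pairs contribute 0)
- local efficiency: per node, global-efficiency-like sum on the neighborhood
  subgraph, (w_ij * w_ih / d_jh(N_i))^(1/3), averaged over all n nodes
- Onnela weighted clustering coefficient, averaged over nodes
- homogeneity index H: mean over clusters of mean within-cluster pairwise z
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path

from .graphs import WeightedGraph

logger = logging.getLogger("ahmo")

__all__ = [
    "NodalMetrics",
    "GlobalMetrics",
    "HomogeneityReport",
    "nodal_strength",
    "betweenness",
    "global_efficiency",
    "local_efficiency",
    "mean_clustering",
    "global_metrics",
    "homogeneity_index",
    "subregional_mean_fc",
    "normalize_across_regions",
]


@dataclass
class NodalMetrics:
    strength: np.ndarray
    betweenness: np.ndarray
    node_ids: np.ndarray
    normalized: bool = False


@dataclass
class GlobalMetrics:
    e_glob: float
    e_loc: float
    mean_cc: float


@dataclass
class HomogeneityReport:
    """Homogeneity index H with per-cluster within-cluster mean z values."""

    H: float
    per_cluster: np.ndarray
    K: int
    sizes: np.ndarray


def _weight_matrix(g: WeightedGraph | np.ndarray) -> np.ndarray:
    return g.weights if isinstance(g, WeightedGraph) else np.asarray(g, float)


def _length_matrix(W: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        L = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), np.inf)
    np.fill_diagonal(L, 0.0)
    return L


def nodal_strength(g: WeightedGraph | np.ndarray) -> np.ndarray:
    """Sum of each node's connection weights."""
    return _weight_matrix(g).sum(axis=1)


def _to_nx(W: np.ndarray, lengths: bool = False) -> nx.Graph:
    G = nx.Graph()
    n = W.shape[0]
    G.add_nodes_from(range(n))
    ii, jj = np.nonzero(np.triu(W, 1))
    for i, j in zip(ii, jj):
        attrs = {"weight": W[i, j]}
        if lengths:
            attrs["length"] = 1.0 / W[i, j]
        G.add_edge(int(i), int(j), **attrs)
    return G


def betweenness(g: WeightedGraph | np.ndarray) -> np.ndarray:
    """Normalized weighted betweenness centrality (lengths = 1/weight).

    Multiple equally short paths are counted fractionally; disconnected
    pairs contribute nothing.
    """
    W = _weight_matrix(g)
    if W.min(initial=0.0) < 0:
        raise ValueError("betweenness requires nonnegative weights")
    n = W.shape[0]
    if n < 3:
        return np.zeros(n)
    G = _to_nx(W, lengths=True)
    bc = nx.betweenness_centrality(G, normalized=True, weight="length")
    return np.array([bc[i] for i in range(n)])


def global_efficiency(g: WeightedGraph | np.ndarray) -> float:
    """Mean inverse shortest-path length over ordered node pairs."""
    W = _weight_matrix(g)
    n = W.shape[0]
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    D = shortest_path(_length_matrix(W), method="D", directed=False)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(D) & (D > 0), 1.0 / np.where(D > 0, D, 1.0), 0.0)
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def local_efficiency(g: WeightedGraph | np.ndarray) -> float:
    """Mean weighted efficiency of each node's neighborhood subgraph.

    Weights are rescaled by the graph maximum; per node i with degree k >= 2,

        e_i = 1/(k(k-1)) * sum_{j != h in N(i)} (w_ij * w_ih / d_jh(N_i))^(1/3)

    with d computed on the subgraph induced by N(i) (lengths 1/w).  Nodes of
    degree < 2 contribute 0; the graph value averages over all n nodes.
    """
    W = _weight_matrix(g)
    if W.min(initial=0.0) < 0:
        raise ValueError("local efficiency requires nonnegative weights")
    n = W.shape[0]
    wmax = W.max(initial=0.0)
    if wmax == 0:
        return 0.0
    Wn = W / wmax
    total = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(Wn[i] > 0)
        k = nbrs.size
        if k < 2:
            continue
        sub = Wn[np.ix_(nbrs, nbrs)]
        D = shortest_path(_length_matrix(sub), method="D", directed=False)
        with np.errstate(divide="ignore"):
            inv_d = np.where(np.isfinite(D) & (D > 0), 1.0 / np.where(D > 0, D, 1.0), 0.0)
        np.fill_diagonal(inv_d, 0.0)
        wi = Wn[i, nbrs]
        contrib = np.cbrt(np.outer(wi, wi) * inv_d)
        np.fill_diagonal(contrib, 0.0)
        total += contrib.sum() / (k * (k - 1))
    return float(total / n)


def mean_clustering(g: WeightedGraph | np.ndarray) -> float:
    """Mean Onnela weighted clustering coefficient (weights / max weight)."""
    W = _weight_matrix(g)
    n = W.shape[0]
    if n == 0 or W.max(initial=0.0) == 0:
        return 0.0
    G = _to_nx(W)
    cc = nx.clustering(G, weight="weight")
    return float(np.mean([cc[i] for i in range(n)]))


def global_metrics(g: WeightedGraph | np.ndarray) -> GlobalMetrics:
    return GlobalMetrics(e_glob=global_efficiency(g),
                         e_loc=local_efficiency(g),
                         mean_cc=mean_clustering(g))


def homogeneity_index(cluster_z_matrices: list) -> HomogeneityReport:
    """H = mean over clusters of the mean within-cluster pairwise z score.

    ``cluster_z_matrices`` holds one symmetric z matrix per cluster (voxels of
    that cluster).  Clusters with fewer than 2 voxels carry no pairwise
    information; they are excluded (and logged), reducing K.
    """
    means = []
    sizes = []
    skipped = 0
    for Z in cluster_z_matrices:
        Z = np.asarray(Z, dtype=float)
        m = Z.shape[0]
        if m < 2:
            skipped += 1
            continue
        off = ~np.eye(m, dtype=bool)
        means.append(Z[off].mean())
        sizes.append(m)
    if skipped:
        logger.info("excluded %d singleton clusters from homogeneity index",
                    skipped)
    if not means:
        raise ValueError("all clusters are singletons; H undefined")
    per_cluster = np.array(means)
    return HomogeneityReport(H=float(per_cluster.mean()),
                             per_cluster=per_cluster,
                             K=len(means), sizes=np.array(sizes))


def subregional_mean_fc(r_sub: np.ndarray, mapping: dict,
                        parent_ids: np.ndarray | None = None) -> np.ndarray:
    """Average subregion-level correlations into a parent-level matrix.

    ``r_sub`` is the subregion correlation matrix (diagonal ignored between
    different parents since all cross-parent pairs are off-diagonal);
    ``mapping`` maps subregion index (row of ``r_sub``) -> parent id.  For
    parents with a single subregion this reduces to the plain correlation.
    The parent-level diagonal is set to 0.
    """
    r_sub = np.asarray(r_sub, dtype=float)
    n = r_sub.shape[0]
    missing = [i for i in range(n) if i not in mapping]
    if missing:
        raise ValueError(f"subregions without parent mapping: {missing}")
    if parent_ids is None:
        parent_ids = np.unique([mapping[i] for i in range(n)])
    parent_ids = np.asarray(parent_ids)
    groups = {p: [i for i in range(n) if mapping[i] == p] for p in parent_ids}
    K = parent_ids.size
    out = np.zeros((K, K))
    for a in range(K):
        for b in range(a + 1, K):
            block = r_sub[np.ix_(groups[parent_ids[a]], groups[parent_ids[b]])]
            out[a, b] = out[b, a] = block.mean()
    return out


def normalize_across_regions(values: np.ndarray, mapping: dict | None = None) -> np.ndarray:
    """Average a nodal measure within parent ROIs, then z-score across ROIs.

    Removes the scale difference induced by graph size so nodal measures from
    parcellations with different node counts can be compared region by
    region.  With a one-to-one mapping this is plain z-scoring.
    Returns the K-vector of z-scores in sorted parent-id order.
    """
    values = np.asarray(values, dtype=float)
    if mapping is None:
        mapping = {i: i for i in range(values.size)}
    parents = np.array([mapping[i] for i in range(values.size)])
    parent_ids = np.unique(parents)
    if parent_ids.size < 2:
        raise ValueError("need at least 2 parent regions to normalize")
    u = np.array([values[parents == p].mean() for p in parent_ids])
    sd = u.std()
    if sd == 0:
        raise ValueError("zero variance across parent regions")
    return (u - u.mean()) / sd
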