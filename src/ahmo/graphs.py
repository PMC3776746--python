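"""Weighted functional-connectivity graph construction.

Pipeline: Pearson correlation graph -> Fisher r-to-z, standardized by
sqrt(Ns - 3) so null edges are N(0, 1) -> group averaging -> thresholding at a
network-forming z cutoff (weights are kept, not binarized; ties at the cutoff
and all negative weights are removed for any cutoff >= 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocess import RegionTimeSeries

logger = logging.getLogger("ahmo")

__all__ = [
    "WeightedGraph",
    "correlation_graph",
    "fisher_z_standardize",
    "group_average",
    "threshold_graph",
    "graph_to_tsv",
    "graph_from_tsv",
]

_SYM_TOL = 1e-10


@dataclass
class WeightedGraph:
    """Symmetric weighted adjacency matrix with node metadata.

    ``standardized`` marks Fisher-z / sqrt(Ns-3) units; ``threshold_z`` records
    the network-forming cutoff once applied (all surviving weights exceed it).
    """

    weights: np.ndarray
    node_ids: np.ndarray = None
    node_parent: dict | None = None
    standardized: bool = False
    threshold_z: float | None = None
    node_centroids: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if np.abs(w - w.T).max(initial=0.0) > _SYM_TOL:
            raise ValueError("weight matrix is not symmetric")
        w = 0.5 * (w + w.T)
        np.fill_diagonal(w, 0.0)
        self.weights = w
        if self.node_ids is None:
            self.node_ids = np.arange(1, w.shape[0] + 1)
        self.node_ids = np.asarray(self.node_ids)
        if self.node_ids.size != w.shape[0]:
            raise ValueError("node_ids length must match matrix size")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))


def correlation_graph(ts: RegionTimeSeries | np.ndarray,
                      node_ids: np.ndarray | None = None,
                      node_parent: dict | None = None) -> WeightedGraph:
    """Pearson correlation matrix over series, diagonal zeroed.

    Accepts a :class:`RegionTimeSeries` or a raw (n_series, t) array.
    Zero-variance series are an error (the offending node is named).
    """
    if isinstance(ts, RegionTimeSeries):
        series = ts.series
        if node_ids is None:
            node_ids = ts.region_ids
    else:
        series = np.atleast_2d(np.asarray(ts, dtype=float))
    if series.shape[1] < 3:
        raise ValueError("need at least 3 time points for correlation")
    sd = series.std(axis=1)
    ids = np.asarray(node_ids) if node_ids is not None else np.arange(1, series.shape[0] + 1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance series for node(s) {ids[dead].tolist()}")
    r = np.corrcoef(series)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return WeightedGraph(weights=r, node_ids=ids, node_parent=node_parent,
                         standardized=False)


def fisher_z_standardize(g: WeightedGraph, ns: int) -> WeightedGraph:
    """Fisher r-to-z, scaled by sqrt(ns - 3) so a null edge is N(0, 1).

    ``ns`` is the temporal sample size of the underlying correlations.
    """
    if ns <= 3:
        raise ValueError("ns must exceed 3")
    off = ~np.eye(g.n_nodes, dtype=bool)
    if np.any(np.abs(g.weights[off]) >= 1.0):
        raise ValueError("|r| >= 1 cannot be z-transformed (infinite z)")
    z = np.arctanh(g.weights) * np.sqrt(ns - 3)
    np.fill_diagonal(z, 0.0)
    return replace(g, weights=z, standardized=True)


def group_average(graphs: list) -> WeightedGraph:
    """Element-wise mean of standardized subject graphs (same node sets)."""
    if not graphs:
        raise ValueError("no graphs to average")
    first = graphs[0]
    for g in graphs:
        if not g.standardized:
            raise ValueError("group averaging requires standardized graphs")
        if g.weights.shape != first.weights.shape or not np.array_equal(
                g.node_ids, first.node_ids):
            raise ValueError("node set mismatch across subject graphs")
    mean = np.mean([g.weights for g in graphs], axis=0)
    return replace(first, weights=mean)


def threshold_graph(g: WeightedGraph, z_thr: float) -> WeightedGraph:
    """Keep weights strictly above ``z_thr``; everything else becomes 0.

    Any cutoff >= 0 removes all negative edges.  An empty surviving graph is
    allowed but logged.
    """
    if not g.standardized:
        raise ValueError("threshold applies to standardized graphs")
    w = np.where(g.weights > z_thr, g.weights, 0.0)
    np.fill_diagonal(w, 0.0)
    if not np.any(w):
        logger.warning("threshold z=%s leaves an empty graph", z_thr)
    return replace(g, weights=w, threshold_z=float(z_thr))


def graph_to_tsv(g: WeightedGraph, path) -> None:
    ids = [str(i) for i in g.node_ids.tolist()]
    pd.DataFrame(g.weights, index=ids, columns=ids).to_csv(path, sep="\t")


def graph_from_tsv(path, standardized: bool = False) -> WeightedGraph:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return WeightedGraph(weights=df.to_numpy(dtype=float),
                         node_ids=np.asarray(df.index),
                         standardized=standardized)
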