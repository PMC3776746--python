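"""Anatomy-constrained hierarchical modularity optimization (AHMO).

Each anatomical region of interest (ROI) is treated as an independent graph
whose nodes are the ROI's voxels and whose edge weights are group-averaged,
standardized Fisher-z voxel-to-voxel correlations (negative averages clamped
to zero).  Newman modularity

    Q = (1/V) * sum_ij (w_ij - s_i * s_j / V) * delta(C_i, C_j)

is maximized per ROI by a seeded Louvain-style greedy optimizer with restarts
and a node-level refinement, where ``s_i`` is node strength and ``V`` the
total weight over ordered pairs.  The sum runs over ordered pairs including
i = j (diagonals are zero, so this only fixes the convention).  Afterwards,
spatially disconnected parts of a cluster are relabelled as new clusters and
clusters smaller than ``min_size`` voxels are merged into the closest cluster
(centroid-to-centroid, millimetres) within the same parent ROI, so the final
parcellation is nested in the anatomical atlas.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .graphs import correlation_graph, fisher_z_standardize, group_average
from .volumes import LabelVolume, Partition, TimeSeriesVolume

logger = logging.getLogger("ahmo")

__all__ = [
    "ModularityModel",
    "AhmoResult",
    "build_roi_voxel_graph",
    "modularity",
    "optimize_modularity",
    "exhaustive_best_partition",
    "repair_contiguity",
    "merge_small_clusters",
    "run_ahmo",
]


@dataclass
class ModularityModel:
    """A nonnegative weighted voxel graph ready for modularity optimization."""

    W: np.ndarray                 # (m, m) symmetric, nonnegative, zero diagonal
    voxel_index: np.ndarray | None = field(default=None, repr=False)  # (m, 3)
    roi: int | None = None

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("W must be square")
        if W.min(initial=0.0) < 0:
            raise ValueError("W must be nonnegative (clamp before optimizing)")
        self.W = W

    @property
    def m(self) -> int:
        return self.W.shape[0]

    @property
    def s(self) -> np.ndarray:
        return self.W.sum(axis=1)

    @property
    def V(self) -> float:
        return float(self.W.sum())


@dataclass
class AhmoResult:
    """Final nested parcellation plus per-ROI best modularity."""

    partition: Partition
    per_roi_Q: dict
    cluster_count: int


def build_roi_voxel_graph(cohort: list, atlas: LabelVolume, roi: int) -> ModularityModel:
    """Group-averaged standardized voxel graph for one anatomical ROI.

    Per subject: voxel-to-voxel Pearson correlations -> Fisher z scaled by
    sqrt(t - 3) -> element-wise group mean; negative averaged weights are
    clamped to zero before optimization.
    """
    mask = atlas.labels == roi
    m = int(mask.sum())
    if m == 0:
        raise ValueError(f"ROI {roi} is empty")
    coords = np.argwhere(mask)
    if m == 1:
        return ModularityModel(W=np.zeros((1, 1)), voxel_index=coords, roi=roi)
    subject_graphs = []
    for vol in cohort:
        series = vol.data[mask]  # (m, t)
        g = correlation_graph(series)
        subject_graphs.append(fisher_z_standardize(g, ns=series.shape[1]))
    avg = group_average(subject_graphs)
    W = np.clip(avg.weights, 0.0, None)
    np.fill_diagonal(W, 0.0)
    return ModularityModel(W=W, voxel_index=coords, roi=roi)


# ---------------------------------------------------------------------------
# Modularity and its optimization
# ---------------------------------------------------------------------------

def modularity(model: ModularityModel, assignment: np.ndarray) -> float:
    """Newman modularity of an assignment (ordered-pair convention)."""
    V = model.V
    if V <= 0:
        raise ValueError("total weight V must be positive")
    labels = _compact_labels(np.asarray(assignment))
    k = labels.max() + 1
    onehot = np.zeros((model.m, k))
    onehot[np.arange(model.m), labels] = 1.0
    w_in = np.einsum("ic,ij,jc->", onehot, model.W, onehot)
    S = np.bincount(labels, weights=model.s, minlength=k)
    return float(w_in / V - np.sum(S * S) / (V * V))


def _compact_labels(labels: np.ndarray) -> np.ndarray:
    _, compact = np.unique(labels, return_inverse=True)
    return compact


def _local_moves(W: np.ndarray, labels: np.ndarray, rng: np.random.Generator,
                 V: float, s: np.ndarray) -> tuple:
    """Greedy single-node moves until no move improves Q.  Returns labels."""
    n = W.shape[0]
    labels = _compact_labels(labels)
    n_comm = labels.max() + 1
    # one spare slot so a node can always split off as a singleton
    tot = np.bincount(labels, weights=s, minlength=n_comm + 1)
    improved = False
    while True:
        moved = 0
        for i in rng.permutation(n):
            ci = labels[i]
            k = np.bincount(labels, weights=W[i], minlength=tot.size)
            tot[ci] -= s[i]
            gain = 2.0 * k / V - 2.0 * s[i] * tot / (V * V)
            best = int(np.argmax(gain))
            if gain[best] > gain[ci] + 1e-12:
                labels[i] = best
                tot[best] += s[i]
                moved += 1
                if best == tot.size - 1:  # used the spare slot; grow
                    tot = np.append(tot, 0.0)
            else:
                tot[ci] += s[i]
        if moved == 0:
            break
        improved = True
    return _compact_labels(labels), improved


def _merge_communities(W: np.ndarray, labels: np.ndarray, V: float,
                       s: np.ndarray) -> np.ndarray:
    """Greedy pairwise community merges while any merge increases Q."""
    labels = _compact_labels(labels)
    while True:
        k = labels.max() + 1
        if k < 2:
            break
        onehot = np.zeros((W.shape[0], k))
        onehot[np.arange(W.shape[0]), labels] = 1.0
        B = onehot.T @ W @ onehot          # between/within community weights
        S = np.bincount(labels, weights=s, minlength=k)
        gain = 2.0 * B / V - 2.0 * np.outer(S, S) / (V * V)
        np.fill_diagonal(gain, -np.inf)
        a, b = np.unravel_index(np.argmax(gain), gain.shape)
        if gain[a, b] <= 1e-12:
            break
        labels[labels == max(a, b)] = min(a, b)
        labels = _compact_labels(labels)
    return labels


def _louvain_once(W: np.ndarray, rng: np.random.Generator,
                  init: np.ndarray | None = None) -> np.ndarray:
    n = W.shape[0]
    V = W.sum()
    W_level = W
    membership = np.arange(n)  # node -> current-level community
    if init is not None:
        # start from a (possibly random) coarse partition, then refine
        s = W.sum(axis=1)
        membership, _ = _local_moves(W, init, rng, V, s)
        k = membership.max() + 1
        onehot = np.zeros((n, k))
        onehot[np.arange(n), membership] = 1.0
        W_level = onehot.T @ W @ onehot
    while True:
        s_level = W_level.sum(axis=1)
        labels, improved = _local_moves(W_level, np.arange(W_level.shape[0]),
                                        rng, V, s_level)
        membership = labels[membership]
        k = labels.max() + 1
        if not improved or k == W_level.shape[0]:
            break
        onehot = np.zeros((W_level.shape[0], k))
        onehot[np.arange(W_level.shape[0]), labels] = 1.0
        W_level = onehot.T @ W_level @ onehot
    # refinement on the original graph from the aggregated solution
    s = W.sum(axis=1)
    membership, _ = _local_moves(W, membership, rng, V, s)
    membership = _merge_communities(W, membership, V, s)
    membership, _ = _local_moves(W, membership, rng, V, s)
    return _compact_labels(membership)


def optimize_modularity(model: ModularityModel, seed: int = 0,
                        restarts: int = 20) -> np.ndarray:
    """Best assignment over seeded restarts (deterministic given ``seed``).

    Falls back to the trivial one-cluster assignment (Q = 0) if no restart
    finds a positive-Q subdivision, so the returned Q is never negative.
    """
    m = model.m
    if m == 1:
        return np.zeros(1, dtype=int)
    if model.V <= 0:
        logger.info("ROI %s has no positive weight; single cluster", model.roi)
        return np.zeros(m, dtype=int)
    children = np.random.SeedSequence(seed).spawn(restarts)
    best_labels = np.zeros(m, dtype=int)
    best_q = 0.0  # one-cluster baseline
    for idx, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        init = None
        if idx > 0:  # diversify restarts with random coarse initializations
            k = int(rng.integers(2, m + 1))
            init = rng.integers(0, k, size=m)
        labels = _louvain_once(model.W, rng, init=init)
        q = modularity(model, labels)
        if q > best_q + 1e-12:
            best_q = q
            best_labels = labels
    return best_labels


def _set_partitions(n: int):
    """All set partitions of range(n) as restricted-growth label vectors."""
    labels = np.zeros(n, dtype=int)

    def rec(i: int, k: int):
        if i == n:
            yield labels.copy()
            return
        for c in range(k + 1):
            labels[i] = c
            yield from rec(i + 1, max(k, c + 1))

    yield from rec(1, 1) if n > 1 else iter([np.zeros(1, dtype=int)])


def exhaustive_best_partition(model: ModularityModel) -> tuple:
    """Exact maximum-Q partition by Bell-number enumeration (small m only)."""
    if model.m > 12:
        raise ValueError("exhaustive search is for small graphs (m <= 12)")
    best_q = -np.inf
    best = None
    for labels in _set_partitions(model.m):
        q = modularity(model, labels)
        if q > best_q + 1e-15:
            best_q = q
            best = labels
    return best, float(best_q)


# ---------------------------------------------------------------------------
# Spatial post-processing
# ---------------------------------------------------------------------------

_STRUCTURES = {6: 1, 18: 2, 26: 3}


def repair_contiguity(p: Partition, connectivity: int = 6) -> Partition:
    """Split spatially disconnected parts of each cluster into new clusters."""
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be one of 6, 18, 26")
    structure = ndimage.generate_binary_structure(3, _STRUCTURES[connectivity])
    out = np.zeros_like(p.labels)
    next_id = 1
    for cid in p.cluster_ids:
        comp, n_comp = ndimage.label(p.labels == cid, structure=structure)
        for c in range(1, n_comp + 1):
            out[comp == c] = next_id
            next_id += 1
    return Partition(labels=out, parent=p.parent, min_size=p.min_size)


def _centroid_mm(coords: np.ndarray, voxel_dims: np.ndarray) -> np.ndarray:
    return coords.mean(axis=0) * voxel_dims


def _cluster_adjacency(labels: np.ndarray) -> dict:
    """Face-adjacency (6-connectivity) between positive clusters."""
    adj: dict = {}
    for axis in range(3):
        a = np.moveaxis(labels, axis, 0)[:-1]
        b = np.moveaxis(labels, axis, 0)[1:]
        touching = (a > 0) & (b > 0) & (a != b)
        for x, y in zip(a[touching].ravel(), b[touching].ravel()):
            adj.setdefault(int(x), set()).add(int(y))
            adj.setdefault(int(y), set()).add(int(x))
    return adj


def merge_small_clusters(p: Partition, min_size: int,
                         voxel_dims: np.ndarray | None = None) -> Partition:
    """Merge clusters below ``min_size`` voxels into the closest neighbor.

    Candidates are clusters in the same parent ROI, preferring spatially
    adjacent ones (so merged clusters stay contiguous); the target is the one
    with the nearest centroid in millimetres, ties going to the larger
    cluster.  Clusters are processed smallest-first, with centroids and sizes
    refreshed after each merge.  A cluster alone in its parent ROI is left as
    is (and flagged) even when undersized.
    """
    if voxel_dims is None:
        voxel_dims = (p.parent.voxel_dims_mm if p.parent is not None
                      else np.ones(3))
    voxel_dims = np.asarray(voxel_dims, dtype=float)
    labels = p.labels.copy()
    parent_of = (p.cluster_parent() if p.parent is not None
                 else {int(c): 0 for c in p.cluster_ids})
    coords = {int(c): np.argwhere(labels == c) for c in p.cluster_ids}
    adj = _cluster_adjacency(labels)
    exempt: set = set()  # undersized but alone in their parent ROI

    while True:
        sizes = {c: len(v) for c, v in coords.items()}
        small = sorted((c for c, n in sizes.items()
                        if n < min_size and c not in exempt),
                       key=lambda c: (sizes[c], c))
        if not small:
            break
        c = small[0]
        siblings = [o for o in coords if o != c and parent_of[o] == parent_of[c]]
        if not siblings:
            logger.info("cluster %d (%d voxels) is alone in parent ROI %d; kept",
                        c, sizes[c], parent_of[c])
            exempt.add(c)
            continue
        adjacent = [o for o in siblings if o in adj.get(c, ())]
        pool = adjacent if adjacent else siblings
        cc = _centroid_mm(coords[c], voxel_dims)
        dists = [(float(np.linalg.norm(_centroid_mm(coords[o], voxel_dims) - cc)),
                  -sizes[o], o) for o in pool]
        target = min(dists)[2]
        labels[labels == c] = target
        coords[target] = np.vstack([coords[target], coords.pop(c)])
        adj_c = adj.pop(c, set())
        for o in adj_c:
            adj[o].discard(c)
            if o != target:
                adj[o].add(target)
                adj.setdefault(target, set()).add(o)
    return Partition(labels=labels, parent=p.parent, min_size=min_size)


def _relabel_sequential(labels: np.ndarray, order_key=None) -> np.ndarray:
    ids = np.unique(labels)
    ids = ids[ids > 0]
    out = np.zeros_like(labels)
    for new, old in enumerate(ids, start=1):
        out[labels == old] = new
    return out


def run_ahmo(cohort: list, atlas: LabelVolume, *, min_size: int = 50,
             connectivity: int = 6, restarts: int = 20, seed: int = 0,
             rois: list | None = None) -> AhmoResult:
    """Full AHMO pipeline over every ROI of an anatomical atlas.

    Per ROI: build group voxel graph -> maximize modularity -> split
    non-contiguous clusters -> merge undersized clusters; final clusters are
    relabelled 1..K globally (in ROI order).  Deterministic given ``seed``.

    Parameters
    ----------
    cohort : list of TimeSeriesVolume
        Preprocessed subject volumes sharing the atlas grid.
    min_size : int
        Smallest allowed cluster, in voxels (50 at acquisition resolution;
        scale down for toy grids).
    """
    for vol in cohort:
        if vol.data.shape[:3] != atlas.labels.shape:
            raise ValueError("cohort volume grid does not match atlas grid")
    roi_ids = [int(r) for r in (rois if rois is not None else atlas.region_ids)]
    seeds = np.random.SeedSequence(seed).spawn(len(roi_ids))
    grid = np.zeros_like(atlas.labels)
    per_roi_Q: dict = {}
    next_id = 1
    for roi, ss in zip(roi_ids, seeds):
        model = build_roi_voxel_graph(cohort, atlas, roi)
        if model.m < 2:
            logger.info("ROI %d has <2 voxels; trivial cluster", roi)
            assignment = np.zeros(model.m, dtype=int)
            per_roi_Q[roi] = 0.0
        else:
            roi_seed = int(ss.generate_state(1)[0] % (2 ** 31))
            assignment = optimize_modularity(model, seed=roi_seed,
                                             restarts=restarts)
            per_roi_Q[roi] = modularity(model, assignment)
        for local in np.unique(assignment):
            sel = model.voxel_index[assignment == local]
            grid[sel[:, 0], sel[:, 1], sel[:, 2]] = next_id
            next_id += 1
    part = Partition(labels=grid, parent=atlas, min_size=1)
    part = repair_contiguity(part, connectivity=connectivity)
    part = merge_small_clusters(part, min_size=min_size,
                                voxel_dims=atlas.voxel_dims_mm)
    final = Partition(labels=_relabel_sequential(part.labels), parent=atlas,
                      min_size=min_size)
    return AhmoResult(partition=final, per_roi_Q=per_roi_Q,
                      cluster_count=final.n_clusters)
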