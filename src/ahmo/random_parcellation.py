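"""Size-matched control parcellation by random seeding and uniform growth.

Seeds are placed uniformly at random in a gray-matter mask and grown with
maximally uniform speed: at every step the currently smallest cluster claims
one random voxel from its frontier (face adjacency).  This yields parcels of
near-equal size that respect spatial contiguity but ignore both anatomy and
function, which is exactly what makes them a useful control: they match a
functional parcellation in node count while carrying no homogeneity
information beyond spatial proximity.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import numpy as np

from .volumes import LabelVolume, Partition

logger = logging.getLogger("ahmo")

__all__ = ["GrowthState", "place_seeds", "grow_uniform", "random_parcellation"]

_FACE_OFFSETS = np.array([
    [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1],
])


@dataclass
class GrowthState:
    """Mutable state of the region-growing process."""

    mask: np.ndarray                       # boolean in-mask voxels
    assigned: np.ndarray                   # int labels, 0 = unassigned
    frontier: list                         # per-cluster list of candidate voxels
    sizes: np.ndarray
    rng: np.random.Generator = field(repr=False, default=None)


def place_seeds(mask: LabelVolume | np.ndarray, n_seeds: int,
                seed: int = 0) -> np.ndarray:
    """Choose ``n_seeds`` distinct in-mask voxels uniformly at random."""
    mask_arr = mask.labels > 0 if isinstance(mask, LabelVolume) else np.asarray(mask) > 0
    voxels = np.argwhere(mask_arr)
    if n_seeds > len(voxels):
        raise ValueError(f"{n_seeds} seeds exceed mask size {len(voxels)}")
    if n_seeds < 1:
        raise ValueError("need at least one seed")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(voxels), size=n_seeds, replace=False)
    return voxels[picks]


def _init_state(mask_arr: np.ndarray, seeds: np.ndarray,
                rng: np.random.Generator) -> GrowthState:
    assigned = np.zeros(mask_arr.shape, dtype=np.int64)
    frontier = [[] for _ in range(len(seeds) + 1)]
    for cid, (x, y, z) in enumerate(seeds, start=1):
        assigned[x, y, z] = cid
    sizes = np.bincount(assigned.ravel(), minlength=len(seeds) + 1)
    state = GrowthState(mask=mask_arr, assigned=assigned, frontier=frontier,
                        sizes=sizes, rng=rng)
    for cid, (x, y, z) in enumerate(seeds, start=1):
        _push_neighbors(state, cid, np.array([x, y, z]))
    return state


def _push_neighbors(state: GrowthState, cid: int, voxel: np.ndarray) -> None:
    shape = state.mask.shape
    for off in _FACE_OFFSETS:
        nb = voxel + off
        if np.any(nb < 0) or np.any(nb >= shape):
            continue
        nb_t = tuple(nb)
        if state.mask[nb_t] and state.assigned[nb_t] == 0:
            state.frontier[cid].append(nb_t)


def grow_uniform(state: GrowthState) -> Partition:
    """Grow all clusters to cover the mask with maximally uniform sizes.

    The smallest cluster (ties by cluster id) expands by one random frontier
    voxel per step.  Voxels unreachable from any seed are assigned to the
    cluster with the nearest centroid at the end (logged).
    """
    n_clusters = len(state.frontier) - 1
    heap = [(int(state.sizes[c]), c) for c in range(1, n_clusters + 1)]
    heapq.heapify(heap)
    rng = state.rng
    while heap:
        size, cid = heapq.heappop(heap)
        if size != state.sizes[cid]:
            continue  # stale entry
        front = state.frontier[cid]
        voxel = None
        while front:
            j = rng.integers(len(front))
            cand = front[j]
            front[j] = front[-1]
            front.pop()
            if state.assigned[cand] == 0:
                voxel = cand
                break
        if voxel is None:
            continue  # cluster can no longer grow
        state.assigned[voxel] = cid
        state.sizes[cid] += 1
        _push_neighbors(state, cid, np.array(voxel))
        heapq.heappush(heap, (int(state.sizes[cid]), cid))

    unreached = state.mask & (state.assigned == 0)
    if unreached.any():
        logger.info("%d voxels unreachable from any seed; assigned to nearest "
                    "cluster centroid", int(unreached.sum()))
        centroids = np.array([np.argwhere(state.assigned == c).mean(axis=0)
                              for c in range(1, n_clusters + 1)])
        for vox in np.argwhere(unreached):
            d = np.linalg.norm(centroids - vox, axis=1)
            state.assigned[tuple(vox)] = int(np.argmin(d)) + 1
    return Partition(labels=state.assigned, min_size=1)


def random_parcellation(mask: LabelVolume | np.ndarray, n_seeds: int,
                        seed: int = 0) -> Partition:
    """Convenience wrapper: place seeds then grow (deterministic by seed)."""
    mask_arr = mask.labels > 0 if isinstance(mask, LabelVolume) else np.asarray(mask) > 0
    seeds = place_seeds(mask_arr, n_seeds, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, n_seeds]))
    state = _init_state(mask_arr, seeds, rng)
    return grow_uniform(state)
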