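"""Core volume types and NIfTI / lookup-table I/O.

All spatial operations work in 0-based voxel indices; millimetre units enter
only through ``voxel_dims_mm`` (for centroid distances).  Label 0 is reserved
for background in every labelled volume.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger("ahmo")

__all__ = [
    "TimeSeriesVolume",
    "LabelVolume",
    "Partition",
    "read_bold",
    "write_bold",
    "read_labels",
    "write_labels",
    "check_nesting",
]


def _voxel_dims_from_affine(affine: np.ndarray) -> np.ndarray:
    return np.sqrt((np.asarray(affine)[:3, :3] ** 2).sum(axis=0))


@dataclass
class TimeSeriesVolume:
    """A 4D BOLD scalar field with grid metadata.

    Parameters
    ----------
    data : ndarray, shape (x, y, z, t)
        Voxel time series.  Must be finite; at least two time points.
    tr_seconds : float
        Repetition time in seconds (time between consecutive volumes).
    affine : ndarray, shape (4, 4)
        Voxel-to-world affine.
    """

    data: np.ndarray
    tr_seconds: float
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data, got {self.data.ndim}D")
        if self.data.shape[3] < 2:
            raise ValueError("need at least 2 time points")
        if any(s < 1 for s in self.data.shape[:3]):
            raise ValueError("all spatial dims must be >= 1")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite voxel values in time-series volume")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_dims_mm(self) -> np.ndarray:
        return _voxel_dims_from_affine(self.affine)


@dataclass
class LabelVolume:
    """A 3D integer label field; 0 is background, positive labels are regions."""

    labels: np.ndarray
    lookup: dict = field(default_factory=dict)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 3:
            raise ValueError(f"expected 3D labels, got {arr.ndim}D")
        if not np.issubdtype(arr.dtype, np.integer):
            flo = np.asarray(arr, dtype=float)
            if not np.allclose(flo, np.round(flo)):
                raise ValueError("label volume contains non-integer values")
            arr = np.round(flo).astype(np.int64)
        if arr.min() < 0:
            raise ValueError("negative labels not allowed")
        self.labels = arr.astype(np.int64)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.lookup:
            missing = set(self.region_ids.tolist()) - {int(k) for k in self.lookup}
            if missing:
                raise ValueError(
                    f"labels present in volume but absent from lookup: {sorted(missing)}"
                )

    @property
    def region_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_regions(self) -> int:
        return int(self.region_ids.size)

    @property
    def voxel_dims_mm(self) -> np.ndarray:
        return _voxel_dims_from_affine(self.affine)

    def region_name(self, label: int) -> str:
        return self.lookup.get(int(label), str(label))


@dataclass
class Partition:
    """Voxel-to-cluster assignment, optionally nested within a parent atlas.

    If ``parent`` is given, every cluster must lie entirely inside one parent
    region (the nesting invariant); ``cluster_parent`` exposes the resulting
    single-valued cluster -> parent-region map.
    """

    labels: np.ndarray
    parent: LabelVolume | None = None
    min_size: int = 1

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 3:
            raise ValueError("partition labels must be 3D")
        self.labels = arr.astype(np.int64)
        if self.min_size < 1:
            raise ValueError("min_size must be a positive integer")
        if self.parent is not None:
            check_nesting(self.labels, self.parent.labels)

    @property
    def cluster_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_clusters(self) -> int:
        return int(self.cluster_ids.size)

    def cluster_parent(self) -> dict:
        if self.parent is None:
            raise ValueError("partition has no parent atlas")
        return check_nesting(self.labels, self.parent.labels)

    def sizes(self) -> dict:
        ids, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))


def check_nesting(child: np.ndarray, parent: np.ndarray) -> dict:
    """Verify the nesting invariant and return the cluster -> parent map.

    Every foreground child voxel must be foreground in the parent, and each
    child cluster must map to exactly one parent region.
    """
    child = np.asarray(child)
    parent = np.asarray(parent)
    if child.shape != parent.shape:
        raise ValueError("child/parent grid shape mismatch")
    fg = child > 0
    if np.any(parent[fg] == 0):
        raise ValueError("child cluster extends into parent background")
    mapping: dict = {}
    for c, p in zip(child[fg].ravel(), parent[fg].ravel()):
        c = int(c)
        p = int(p)
        prev = mapping.setdefault(c, p)
        if prev != p:
            raise ValueError(f"cluster {c} spans parent regions {prev} and {p}")
    return mapping


# ---------------------------------------------------------------------------
# NIfTI / lookup I/O
# ---------------------------------------------------------------------------

def read_bold(path: str | Path) -> TimeSeriesVolume:
    """Read a 4D BOLD NIfTI file; TR is taken from the header time zoom."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected 4D BOLD data, got {data.ndim}D in {path}")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"NaN/inf voxels in {path}")
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) >= 4 else 0.0
    if tr <= 0:
        raise ValueError(f"non-positive TR in header of {path}")
    return TimeSeriesVolume(data=data, tr_seconds=tr, affine=img.affine)


def write_bold(vol: TimeSeriesVolume, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(vol.data.astype(np.float64), vol.affine)
    img.header.set_zooms((*vol.voxel_dims_mm, vol.tr_seconds))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    return path


def _read_lookup(lookup_path: str | Path) -> dict:
    lookup_path = Path(lookup_path)
    if lookup_path.suffix == ".json":
        raw = json.loads(lookup_path.read_text())
        return {int(k): str(v) for k, v in raw.items()}
    lookup: dict = {}
    for line in lookup_path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, name = line.partition("\t")
        lookup[int(key)] = name.strip()
    return lookup


def read_labels(path: str | Path, lookup_path: str | Path | None = None) -> LabelVolume:
    """Read a 3D integer atlas and (optionally) its label -> name lookup."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3D label data, got {data.ndim}D in {path}")
    lookup = _read_lookup(lookup_path) if lookup_path is not None else {}
    return LabelVolume(labels=data, lookup=lookup, affine=img.affine)


def write_labels(p: Partition | LabelVolume, ref: LabelVolume, path: str | Path) -> Path:
    """Write a label volume/partition next to a reference grid.

    The reference supplies the affine and is used to assert grid agreement
    (and, for nested partitions, the nesting invariant).
    """
    labels = p.labels
    if labels.shape != ref.labels.shape:
        raise ValueError("grid shape mismatch between partition and reference")
    if isinstance(p, Partition) and p.parent is not None:
        check_nesting(labels, p.parent.labels)
    img = nib.Nifti1Image(labels.astype(np.int32), ref.affine)
    nib.save(img, str(path))
    return Path(path)
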