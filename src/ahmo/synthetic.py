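"""Synthetic resting-state cohorts with planted subregional structure.

Each toy anatomical ROI is split into contiguous planted subregions, each
driven by its own latent signal.  Latents are band-limited (0.009-0.08 Hz)
filtered Gaussian noise -- so their spectra resemble band-passed resting
BOLD -- mixed to a prescribed correlation structure that can include
anti-correlated subregion pairs inside one ROI (the node-inhomogeneity
scenario: a region whose mean signal hides strong subregional
connectivity).  Every voxel carries its subregion's latent plus independent
white noise.  Subjects are independent realizations of the same covariance.

The default cohort (12 x 12 x 6 grid at 3 mm, 6 ROIs with 2-4 subregions
each, 20 subjects, 160 time points at TR = 2 s, voxel noise SD 1.0) plants
three distributed "networks": each subregion loads +/-0.8 on one of three
latent factors, giving within-network correlations of +/-0.64, anti-phase
subregion pairs inside several ROIs, and zero cross-network correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .preprocess import bandpass_array
from .volumes import LabelVolume, Partition, TimeSeriesVolume

logger = logging.getLogger("ahmo")

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "default_factor_loadings",
    "loadings_to_corr",
    "make_toy_atlas",
    "simulate_cohort",
    "connectivity_bias_spec",
]

_DEFAULT_LOADING = 0.8


def default_factor_loadings(subregions_per_roi) -> np.ndarray:
    """Default (S x 3) factor loading matrix over all planted subregions.

    ROI ``r`` primarily belongs to network factor ``r mod 3``: its first
    (dominant, double-sized; see :func:`make_toy_atlas`) subregion loads
    +0.8 on that factor and its second subregion loads -0.8 -- the
    node-inhomogeneity scenario in which averaging over a region partially
    cancels its subregional signal.  Because the first subregion is larger,
    regional means retain attenuated network signal rather than cancelling
    exactly, as in real resting fMRI.  Any further subregions load +0.8 on
    the other factors in turn, so larger anatomical regions participate in
    several functional networks.  Same-network subregions correlate at
    +/-0.64 across ROI boundaries; cross-network correlations are zero;
    distinct subregions stay distinct through their unique variance
    (same-network, same-sign pairs correlate at 0.64, not 1).
    """
    rows = []
    for r, m in enumerate(subregions_per_roi):
        for j in range(m):
            factor = (r + max(0, j - 1)) % 3
            sign = -1.0 if j == 1 else 1.0
            load = np.zeros(3)
            load[factor] = sign * _DEFAULT_LOADING
            rows.append(load)
    return np.array(rows)


def loadings_to_corr(L: np.ndarray) -> np.ndarray:
    """Latent correlation implied by a factor model with unit total variance."""
    L = np.atleast_2d(np.asarray(L, dtype=float))
    comm = (L ** 2).sum(axis=1)
    if np.any(comm > 1.0 + 1e-12):
        raise ValueError("factor loadings imply variance > 1")
    C = L @ L.T + np.diag(1.0 - comm)
    return C


@dataclass
class SyntheticSpec:
    """Study-design parameters of a synthetic cohort."""

    shape: tuple = (12, 12, 6)
    n_rois: int = 6
    subregions_per_roi: tuple = (2, 3, 4, 2, 3, 4)
    n_subjects: int = 20
    n_timepoints: int = 160
    tr_seconds: float = 2.0
    noise_sd: float = 1.0
    latent_corr: np.ndarray | None = None  # between-subregion correlation
    factor_loadings: np.ndarray | None = None
    subject_strength_sd: float = 0.15
    dominant_subregion_weight: float = 2.0
    low_hz: float = 0.009
    high_hz: float = 0.08
    voxel_mm: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.subregions_per_roi, int):
            self.subregions_per_roi = (self.subregions_per_roi,) * self.n_rois
        self.subregions_per_roi = tuple(int(m) for m in self.subregions_per_roi)
        if len(self.subregions_per_roi) != self.n_rois:
            raise ValueError("one subregion count per ROI required")
        if self.n_timepoints < 10:
            raise ValueError("n_timepoints must be >= 10")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.latent_corr is not None and self.factor_loadings is not None:
            raise ValueError("give latent_corr or factor_loadings, not both")
        if self.latent_corr is None and self.factor_loadings is None:
            self.factor_loadings = default_factor_loadings(
                self.subregions_per_roi)
        if self.factor_loadings is not None:
            self.factor_loadings = np.atleast_2d(
                np.asarray(self.factor_loadings, dtype=float))
            self.latent_corr = loadings_to_corr(self.factor_loadings)
        self.latent_corr = np.asarray(self.latent_corr, dtype=float)
        S = self.n_subregions
        if self.latent_corr.shape != (S, S):
            raise ValueError(
                f"latent_corr must be {S} x {S} (one row per planted subregion)")
        eig = np.linalg.eigvalsh(self.latent_corr)
        if eig.min() < -1e-8:
            raise ValueError("latent correlation matrix is not positive "
                             f"semi-definite (min eigenvalue {eig.min():.3g})")

    @property
    def n_subregions(self) -> int:
        return int(sum(self.subregions_per_roi))

    @property
    def within_subregion_corr(self) -> float:
        """Expected voxel-voxel correlation inside a subregion (unit latents)."""
        return 1.0 / (1.0 + self.noise_sd ** 2)

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_mm
        return aff


@dataclass
class GroundTruth:
    """Planted subregion labels and (after simulation) the latent signals."""

    partition: Partition
    latent_corr: np.ndarray
    latents: list = field(default_factory=list)  # one (t, S) matrix per subject

    @property
    def subregion_parent(self) -> dict:
        return self.partition.cluster_parent()


def _split_box(box: tuple, weights) -> list:
    """Split a box into contiguous sub-boxes with sizes ~ proportional to weights."""
    weights = list(weights)
    if len(weights) == 1:
        return [box]
    (x0, x1), (y0, y1), (z0, z1) = box
    extents = [x1 - x0, y1 - y0, z1 - z0]
    axis = int(np.argmax(extents))
    k1 = len(weights) // 2
    frac = sum(weights[:k1]) / sum(weights)
    lo, hi = box[axis]
    cut = lo + min(max(1, round((hi - lo) * frac)), hi - lo - 1)
    left = list(box)
    right = list(box)
    left[axis] = (lo, cut)
    right[axis] = (cut, hi)
    return (_split_box(tuple(left), weights[:k1])
            + _split_box(tuple(right), weights[k1:]))


def make_toy_atlas(spec: SyntheticSpec) -> tuple:
    """Build the toy anatomical atlas and its planted subregion partition.

    ROIs are contiguous axis-aligned blocks tiling the grid; each ROI is
    further bisected into its planted subregions.  Purely deterministic
    given the spec (the geometry carries no randomness).
    """
    nx, ny, nz = spec.shape
    full = ((0, nx), (0, ny), (0, nz))
    roi_boxes = _split_box(full, [1.0] * spec.n_rois)
    atlas = np.zeros(spec.shape, dtype=np.int64)
    subs = np.zeros(spec.shape, dtype=np.int64)
    sub_id = 1
    for roi_label, (roi_box, m) in enumerate(
            zip(roi_boxes, spec.subregions_per_roi), start=1):
        (x0, x1), (y0, y1), (z0, z1) = roi_box
        n_vox = (x1 - x0) * (y1 - y0) * (z1 - z0)
        if n_vox < m:
            raise ValueError(
                f"grid too small: ROI {roi_label} has {n_vox} voxels for {m} "
                "subregions")
        atlas[x0:x1, y0:y1, z0:z1] = roi_label
        sub_weights = [spec.dominant_subregion_weight] + [1.0] * (m - 1)
        for sub_box in _split_box(roi_box, sub_weights):
            (sx0, sx1), (sy0, sy1), (sz0, sz1) = sub_box
            subs[sx0:sx1, sy0:sy1, sz0:sz1] = sub_id
            sub_id += 1
    lookup = {i: f"roi_{i:02d}" for i in range(1, spec.n_rois + 1)}
    label_vol = LabelVolume(labels=atlas, lookup=lookup, affine=spec.affine)
    truth = GroundTruth(
        partition=Partition(labels=subs, parent=label_vol, min_size=1),
        latent_corr=spec.latent_corr)
    return label_vol, truth


def _subject_corr(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """A subject's latent correlation: spec structure, individual strength.

    Real cohorts vary in how strongly each network is expressed; one scalar
    per factor rescales that factor's loadings by
    1 + subject_strength_sd * N(0, 1) (clipped so communalities stay below
    1).  With an explicit ``latent_corr`` (no loadings) the matrix is shared
    by all subjects.
    """
    if spec.factor_loadings is None or spec.subject_strength_sd == 0:
        return spec.latent_corr
    comm_max = float((spec.factor_loadings ** 2).sum(axis=1).max())
    hi = np.sqrt(0.98 / comm_max) if comm_max > 0 else 1.0
    n_factors = spec.factor_loadings.shape[1]
    scale = np.clip(1.0 + spec.subject_strength_sd
                    * rng.standard_normal(n_factors), 0.5, hi)
    return loadings_to_corr(spec.factor_loadings * scale[None, :])


def _draw_latents(spec: SyntheticSpec, rng: np.random.Generator,
                  corr: np.ndarray) -> np.ndarray:
    """One subject's (t, S) band-limited latent matrix with corr ~ ``corr``."""
    S = spec.n_subregions
    white = rng.standard_normal((spec.n_timepoints, S))
    filt = bandpass_array(white, spec.low_hz, spec.high_hz, spec.tr_seconds,
                          axis=0)
    filt = (filt - filt.mean(axis=0)) / filt.std(axis=0)
    # mix to the target correlation; jitter guards exact semi-definiteness
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(S))
    mixed = filt @ chol.T
    return (mixed - mixed.mean(axis=0)) / mixed.std(axis=0)


def simulate_cohort(spec: SyntheticSpec, truth: GroundTruth) -> list:
    """Simulate the cohort: per subject, latents plus white voxel noise.

    Fills ``truth.latents`` with each subject's latent matrix and returns a
    list of :class:`TimeSeriesVolume`.  Deterministic given ``spec.seed``.
    """
    sub_labels = truth.partition.labels
    sub_ids = truth.partition.cluster_ids
    if sub_ids.size != spec.n_subregions:
        raise ValueError("ground-truth partition does not match spec")
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    cohort = []
    truth.latents = []
    col_of = {int(s): i for i, s in enumerate(sub_ids)}
    flat_sub = sub_labels.ravel()
    fg = flat_sub > 0
    col_idx = np.array([col_of[int(s)] for s in flat_sub[fg]])
    for _ in range(spec.n_subjects):
        corr_s = _subject_corr(spec, rng)
        latents = _draw_latents(spec, rng, corr_s)  # (t, S)
        data = np.zeros((flat_sub.size, spec.n_timepoints))
        data[fg] = latents.T[col_idx]
        if spec.noise_sd > 0:
            data[fg] += spec.noise_sd * rng.standard_normal(
                (int(fg.sum()), spec.n_timepoints))
        vol = TimeSeriesVolume(
            data=data.reshape(*spec.shape, spec.n_timepoints),
            tr_seconds=spec.tr_seconds, affine=spec.affine)
        cohort.append(vol)
        truth.latents.append(latents)
    return cohort


def connectivity_bias_spec(seed: int = 0, n_subjects: int = 20,
                           anti_corr: float = 0.9,
                           target_corr: float = 0.7) -> SyntheticSpec:
    """Spec for the mean-signal connectivity-bias scenario.

    One ROI holds two equal-sized anti-correlated subregions (a1, a2 with
    corr -``anti_corr``); a second single-subregion ROI tracks their
    difference (corr +/-``target_corr`` with a1/a2), so its correlation with
    the first ROI's *mean* signal vanishes exactly while subregion-level
    connectivity is strong.  A third, independent ROI serves as filler.
    """
    c = np.sqrt(anti_corr)
    beta = target_corr / c
    if beta >= 1:
        raise ValueError("target_corr too large for the given anti_corr")
    # loadings on factors (g, f_filler)
    L = np.array([
        [c, 0.0],      # a1: first subregion of ROI 1
        [-c, 0.0],     # a2: second subregion of ROI 1
        [beta, 0.0],   # b:  ROI 2 (target region)
        [0.0, 0.8],    # filler ROI 3
    ])
    return SyntheticSpec(shape=(12, 12, 6), n_rois=3,
                         subregions_per_roi=(2, 1, 1), n_subjects=n_subjects,
                         factor_loadings=L, dominant_subregion_weight=1.0,
                         subject_strength_sd=0.0, seed=seed)
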