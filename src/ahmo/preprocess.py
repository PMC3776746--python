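"""Post-alignment signal conditioning for resting-state BOLD data.

Covers the standard connectivity preprocessing chain applied after spatial
preprocessing: dropping initial unstable scans, temporal band-pass filtering
(default 0.009-0.08 Hz), nuisance-confound regression, and extraction of a
representative time series per region (voxel mean or first eigenvariate).

The filter is a zero-phase forward-backward Butterworth (order 2), which
preserves correlation structure; confounds are filtered identically before
regression so regression cannot reintroduce excluded frequencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .volumes import LabelVolume, Partition, TimeSeriesVolume

logger = logging.getLogger("ahmo")

__all__ = [
    "ConfoundSet",
    "RegionTimeSeries",
    "drop_initial_scans",
    "bandpass",
    "bandpass_array",
    "regress_confounds",
    "extract_regional_ts",
]


@dataclass
class ConfoundSet:
    """Nuisance regressors (motion parameters, tissue/global means, ...)."""

    regressors: np.ndarray  # (t, q)
    names: list

    def __post_init__(self) -> None:
        self.regressors = np.atleast_2d(np.asarray(self.regressors, dtype=float))
        if self.regressors.ndim != 2:
            raise ValueError("regressors must be a t x q matrix")
        if len(self.names) != self.regressors.shape[1]:
            raise ValueError("number of names must match number of columns")


@dataclass
class RegionTimeSeries:
    """Representative time series per region: a K x t matrix."""

    series: np.ndarray
    region_ids: np.ndarray
    method: str

    def __post_init__(self) -> None:
        self.series = np.atleast_2d(np.asarray(self.series, dtype=float))
        self.region_ids = np.asarray(self.region_ids)
        if self.series.shape[0] != self.region_ids.size:
            raise ValueError("one series per region id required")
        if not np.all(np.isfinite(self.series)):
            raise ValueError("non-finite values in regional time series")

    @property
    def n_regions(self) -> int:
        return self.series.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.series.shape[1]


def drop_initial_scans(v: TimeSeriesVolume, n_drop: int) -> TimeSeriesVolume:
    """Discard the first ``n_drop`` volumes (scanner stabilization)."""
    if n_drop < 0:
        raise ValueError("n_drop must be non-negative")
    if n_drop >= v.n_timepoints:
        raise ValueError(f"cannot drop {n_drop} of {v.n_timepoints} scans")
    if n_drop == 0:
        return v
    return replace(v, data=v.data[..., n_drop:])


def _design_bandpass(low_hz: float, high_hz: float, tr_seconds: float):
    nyquist = 0.5 / tr_seconds
    if not (0.0 <= low_hz < high_hz):
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(f"high_hz {high_hz} must be below Nyquist {nyquist}")
    fs = 1.0 / tr_seconds
    if low_hz > 0:
        return signal.butter(2, [low_hz, high_hz], btype="bandpass", fs=fs)
    return signal.butter(2, high_hz, btype="lowpass", fs=fs)


def bandpass_array(x: np.ndarray, low_hz: float, high_hz: float, tr_seconds: float,
                   axis: int = -1) -> np.ndarray:
    """Zero-phase Butterworth band-pass along ``axis`` (series x time arrays)."""
    b, a = _design_bandpass(low_hz, high_hz, tr_seconds)
    return signal.filtfilt(b, a, np.asarray(x, dtype=float), axis=axis)


def bandpass(v: TimeSeriesVolume, low_hz: float = 0.009, high_hz: float = 0.08) -> TimeSeriesVolume:
    """Band-pass every voxel time series; removes DC when ``low_hz > 0``."""
    filtered = bandpass_array(v.data, low_hz, high_hz, v.tr_seconds, axis=-1)
    return replace(v, data=filtered)


def regress_confounds(v: TimeSeriesVolume, c: ConfoundSet) -> TimeSeriesVolume:
    """Regress confound columns (plus an intercept) out of every voxel series.

    Residuals are orthogonal to the regressors.  Rank-deficient designs are
    handled with the pseudo-inverse (with a warning).
    """
    t = v.n_timepoints
    if c.regressors.shape[0] != t:
        raise ValueError(
            f"confound rows ({c.regressors.shape[0]}) != time points ({t})"
        )
    X = np.column_stack([np.ones(t), c.regressors])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        logger.warning("rank-deficient confound design (rank %d of %d); "
                       "using pseudo-inverse", rank, X.shape[1])
    Y = v.data.reshape(-1, t).T  # (t, voxels)
    beta = np.linalg.pinv(X) @ Y
    resid = Y - X @ beta
    return replace(v, data=resid.T.reshape(v.data.shape))


def _eigenvariate(voxels_by_time: np.ndarray) -> np.ndarray:
    """First principal component of the centered voxel x time matrix.

    Sign is fixed so correlation with the regional mean is non-negative, and
    the output is rescaled to the mean series' standard deviation, so the
    eigenvariate reads as a variance-maximizing weighted mean.
    """
    mean_series = voxels_by_time.mean(axis=0)
    centered = voxels_by_time - voxels_by_time.mean(axis=1, keepdims=True)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    comp = vt[0]
    mean_centered = mean_series - mean_series.mean()
    if comp @ mean_centered < 0:
        comp = -comp
    sd_mean = mean_centered.std()
    sd_comp = comp.std()
    if sd_comp > 0 and sd_mean > 0:
        comp = comp * (sd_mean / sd_comp)
    return comp + mean_series.mean()


def extract_regional_ts(v: TimeSeriesVolume, p: LabelVolume | Partition,
                        method: str = "mean",
                        region_ids: np.ndarray | None = None) -> RegionTimeSeries:
    """Extract one representative series per labelled region.

    ``method='mean'`` is the arithmetic voxel average; ``method='eigenvariate'``
    the first principal component of the region's voxel x time matrix.
    """
    if method not in ("mean", "eigenvariate"):
        raise ValueError(f"unknown method {method!r}")
    labels = p.labels
    if labels.shape != v.data.shape[:3]:
        raise ValueError("label grid does not match volume grid")
    if region_ids is None:
        ids = np.unique(labels)
        region_ids = ids[ids > 0]
    region_ids = np.asarray(region_ids)
    out = np.empty((region_ids.size, v.n_timepoints))
    for row, rid in enumerate(region_ids):
        mask = labels == rid
        if not mask.any():
            raise ValueError(f"region {int(rid)} has no voxels")
        vox = v.data[mask]  # (m, t)
        if method == "mean" or vox.shape[0] == 1:
            out[row] = vox.mean(axis=0)
        else:
            out[row] = _eigenvariate(vox)
    return RegionTimeSeries(series=out, region_ids=region_ids, method=method)
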