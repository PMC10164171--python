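"""LCMV spatial filtering: source reconstruction from sensor covariance.

A scalar (max-power orientation) linearly constrained minimum-variance
beamformer: for voxel lead field L (channels x 3) and regularized sensor
covariance C_r = C + reg * mean(diag C) * I, the source orientation is the
principal eigenvector of (L' C_r^-1 L)^-1 and the filter
w = (l' C_r^-1 l)^-1 l' C_r^-1 satisfies the unit-gain constraint
w . l = 1 at its own voxel.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .containers import LeadField, SensorEpochs, SpatialFilter


def covariance_from_average(
    epochs: SensorEpochs,
    window: Optional[tuple[float, float]] = None,
    conditions: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Channel covariance of the time-locked average over a time window.

    The average is over trials (optionally restricted to ``conditions``);
    the covariance is over time samples of that average.  After average
    referencing this matrix is rank-deficient by one, which the LCMV
    regularization absorbs.
    """
    data = epochs.data
    if conditions is not None:
        sel = np.isin(epochs.condition_labels.astype(str), list(conditions))
        if not sel.any():
            raise ValueError("no trials in requested conditions")
        data = data[sel]
    if window is not None:
        m = (epochs.times >= window[0]) & (epochs.times <= window[1])
        if not m.any():
            raise ValueError("window outside epoch")
        data = data[:, :, m]
    avg = data.mean(axis=0)  # (channels, times)
    avg = avg - avg.mean(axis=1, keepdims=True)
    n = avg.shape[1]
    return avg @ avg.T / max(n - 1, 1)


def covariance_from_trials(
    epochs: SensorEpochs,
    window: Optional[tuple[float, float]] = None,
    conditions: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Pooled single-trial channel covariance over a time window.

    For induced (non-phase-locked) oscillations the time-locked average
    carries no signal, so the covariance of the average degenerates to
    noise and an LCMV filter built from it cannot null interfering
    sources.  The single-trial estimator keeps the full source covariance
    and is the appropriate choice for induced activity; the average-based
    estimator above matches the classical recipe for phase-locked data.
    """
    data = epochs.data
    if conditions is not None:
        sel = np.isin(epochs.condition_labels.astype(str), list(conditions))
        if not sel.any():
            raise ValueError("no trials in requested conditions")
        data = data[sel]
    if window is not None:
        m = (epochs.times >= window[0]) & (epochs.times <= window[1])
        if not m.any():
            raise ValueError("window outside epoch")
        data = data[:, :, m]
    d = data - data.mean(axis=2, keepdims=True)
    n_trials, n_chan, n_times = d.shape
    flat = d.transpose(1, 0, 2).reshape(n_chan, -1)
    return flat @ flat.T / max(flat.shape[1] - 1, 1)


def lcmv_filters(
    leadfield: LeadField,
    covariance: np.ndarray,
    reg_fraction: float = 0.05,
) -> SpatialFilter:
    """Scalar LCMV filters for every voxel.

    Voxels whose 3x3 source covariance is numerically singular are flagged
    (``voxel_ok = False``) and carry zero weights; downstream code excludes
    them.
    """
    C = np.asarray(covariance, float)
    n_chan = C.shape[0]
    if leadfield.n_channels != n_chan:
        raise ValueError("lead field / covariance channel mismatch")
    Cr = C + reg_fraction * np.trace(C) / n_chan * np.eye(n_chan)
    Ci = np.linalg.inv(Cr)
    V = leadfield.n_voxels
    n_ori = leadfield.gain.shape[2]
    weights = np.zeros((V, n_chan))
    orientations = np.zeros((V, 3))
    ok = np.ones(V, bool)
    for v in range(V):
        L = leadfield.gain[:, v, :]  # (channels, n_ori)
        if n_ori == 1:
            ori = np.array([1.0])
        else:
            CiL = Ci @ L
            G = L.T @ CiL  # (n_ori, n_ori)
            try:
                Ginv = np.linalg.inv(G)
            except np.linalg.LinAlgError:
                ok[v] = False
                continue
            if np.linalg.cond(G) > 1e12:
                ok[v] = False
                continue
            # max-power orientation: principal eigenvector of (L' C^-1 L)^-1
            evals, evecs = np.linalg.eigh(Ginv)
            ori = evecs[:, np.argmax(evals)]
        l = L @ ori  # noqa: E741 - lead field column for chosen orientation
        denom = l @ Ci @ l
        if denom <= 0 or not np.isfinite(denom):
            ok[v] = False
            continue
        weights[v] = (Ci @ l) / denom
        orientations[v, : len(ori)] = ori
    return SpatialFilter(
        weights=weights,
        orientations=orientations,
        regularization=reg_fraction,
        voxel_ok=ok,
    )


def apply_filters(filters: SpatialFilter, epochs: SensorEpochs) -> np.ndarray:
    """Project sensor epochs to source space: (trials, voxels, times)."""
    if filters.weights.shape[1] != epochs.n_channels:
        raise ValueError("channel count mismatch between filters and epochs")
    return np.einsum("vc,tcn->tvn", filters.weights, epochs.data)


def select_voxels(leadfield: LeadField, filters: Optional[SpatialFilter] = None) -> np.ndarray:
    """Labeled, non-cerebellar (and numerically valid) voxel indices."""
    idx = leadfield.included_voxels()
    if filters is not None:
        idx = idx[filters.voxel_ok[idx]]
        if idx.size == 0:
            raise ValueError("no voxels left after filter validity check")
    return idx
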