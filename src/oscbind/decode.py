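"""Multivariate pattern analysis of source-level band-power courses.

All decoders are binary L1-regularized linear SVMs with stratified k-fold
cross-validation; performance is the area under the ROC curve computed
from decision values pooled over held-out folds.  Features are z-scored
with training-fold statistics only.  Variants:

* temporal decoding — voxel pattern at each time sample;
* temporal generalization — train at one time, test at all times;
* cross-band transfer — train on theta features, test on alpha features
  of held-out trials (folds are split once on trials, so no trial is ever
  in both roles);
* spatial decoding — per voxel, the time course restricted to the
  significant time samples as features, yielding an AUC map over voxels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import warnings

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from . import cluster_stats
from .containers import ClusterReport, DecodingConfig


def _binary_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(str)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    # "overlap" coded 1 where recognizable, else lexicographic
    ov = [c for c in classes if c.endswith("_overlap") or c == "overlap"]
    pos = ov[0] if len(ov) == 1 else classes[1]
    return (labels == pos).astype(int)


def _folds(y: np.ndarray, config: DecodingConfig):
    skf = StratifiedKFold(
        n_splits=config.n_folds, shuffle=True, random_state=config.seed
    )
    return list(skf.split(np.zeros(len(y)), y))


def _fit_svm(Xtr: np.ndarray, ytr: np.ndarray, config: DecodingConfig) -> LinearSVC:
    # explicit random_state: liblinear otherwise draws from a process-global
    # RNG, which would make results depend on fit order
    clf = LinearSVC(
        penalty="l1", dual=False, C=config.c_param, max_iter=20000, tol=1e-3,
        random_state=config.seed % 2**31,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(Xtr, ytr)
    return clf


def _standardizer(Xtr: np.ndarray):
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mu, sd


def temporal_mvpa(
    course: np.ndarray,
    labels: np.ndarray,
    config: DecodingConfig,
    time_indices: Optional[np.ndarray] = None,
    test_course: Optional[np.ndarray] = None,
) -> np.ndarray:
    """AUC per time sample from the voxel pattern at that sample.

    With ``test_course`` the classifier trains on ``course`` and is
    evaluated on held-out trials of ``test_course`` at the same time
    sample (cross-band transfer along the diagonal).
    """
    y = _binary_labels(labels)
    if np.bincount(y).min() < config.n_folds:
        raise ValueError("each class needs at least n_folds trials")
    tc = course if test_course is None else np.asarray(test_course)
    if tc.shape != course.shape:
        raise ValueError("train and test courses must share shape")
    T = course.shape[2]
    tids = np.arange(T) if time_indices is None else np.asarray(time_indices)
    folds = _folds(y, config)
    auc = np.zeros(len(tids))
    for k, t in enumerate(tids):
        dec = np.zeros(len(y))
        for tr, te in folds:
            X = course[:, :, t]
            mu, sd = _standardizer(X[tr])
            clf = _fit_svm((X[tr] - mu) / sd, y[tr], config)
            m2, s2 = _standardizer(tc[tr][:, :, t])
            dec[te] = clf.decision_function((tc[te][:, :, t] - m2) / s2)
        auc[k] = roc_auc_score(y, dec)
    return auc


def temporal_generalization(
    course: np.ndarray,
    labels: np.ndarray,
    config: DecodingConfig,
    time_indices: Optional[np.ndarray] = None,
    test_course: Optional[np.ndarray] = None,
) -> np.ndarray:
    """AUC matrix (train time x test time).

    With ``test_course`` given, training features come from ``course`` and
    held-out testing features from ``test_course`` (cross-band transfer);
    both must share trials and time axis.  Test features at each test time
    are standardized with training-fold statistics of that time.
    """
    y = _binary_labels(labels)
    if np.bincount(y).min() < config.n_folds:
        raise ValueError("each class needs at least n_folds trials")
    tc = course if test_course is None else np.asarray(test_course)
    if tc.shape != course.shape:
        raise ValueError("train and test courses must share shape")
    T = course.shape[2]
    tids = np.arange(T) if time_indices is None else np.asarray(time_indices)
    folds = _folds(y, config)
    n = len(y)
    dec = np.zeros((n, len(tids), len(tids)))
    for tr, te in folds:
        # per-test-time standardizers from the training fold of the test course
        te_stats = [_standardizer(tc[tr][:, :, t]) for t in tids]
        for i, t_train in enumerate(tids):
            mu, sd = _standardizer(course[tr][:, :, t_train])
            clf = _fit_svm((course[tr][:, :, t_train] - mu) / sd, y[tr], config)
            w, b = clf.coef_[0], clf.intercept_[0]
            for j, t_test in enumerate(tids):
                m2, s2 = te_stats[j]
                dec[te, i, j] = ((tc[te][:, :, t_test] - m2) / s2) @ w + b
    auc = np.zeros((len(tids), len(tids)))
    for i in range(len(tids)):
        for j in range(len(tids)):
            auc[i, j] = roc_auc_score(y, dec[:, i, j])
    return auc


def cross_band_mvpa(
    train_course: np.ndarray,
    test_course: np.ndarray,
    labels: np.ndarray,
    config: DecodingConfig,
    time_indices: Optional[np.ndarray] = None,
) -> dict:
    """Theta-train / alpha-test transfer decoding.

    Returns ``{"auc_time": ..., "auc_gen": ...}``; the time curve is the
    diagonal of the generalization matrix (train and test at the same
    sample, features from the two different bands).
    """
    gen = temporal_generalization(
        train_course, labels, config, time_indices=time_indices, test_course=test_course
    )
    return {"auc_time": np.diag(gen).copy(), "auc_gen": gen}


def spatial_mvpa(
    course: np.ndarray,
    labels: np.ndarray,
    sig_time_mask: np.ndarray,
    config: DecodingConfig,
    voxel_indices: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-voxel AUC using the time course at significant samples as features."""
    sig_time_mask = np.asarray(sig_time_mask, bool)
    if not sig_time_mask.any():
        raise ValueError("significant-time mask is empty")
    y = _binary_labels(labels)
    vids = (
        np.arange(course.shape[1]) if voxel_indices is None else np.asarray(voxel_indices)
    )
    folds = _folds(y, config)
    auc = np.zeros(len(vids))
    for k, v in enumerate(vids):
        X = course[:, v, :][:, sig_time_mask]
        dec = np.zeros(len(y))
        for tr, te in folds:
            mu, sd = _standardizer(X[tr])
            clf = _fit_svm((X[tr] - mu) / sd, y[tr], config)
            dec[te] = clf.decision_function((X[te] - mu) / sd)
        auc[k] = roc_auc_score(y, dec)
    return auc


def reinsert_voxel_map(
    auc_voxel: np.ndarray, included: np.ndarray, n_voxels: int, chance: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Re-insert an included-voxel AUC vector into the full grid.

    Excluded positions get 0 in both the AUC map and the paired
    chance-level map (which carries ``chance`` at included positions).
    """
    included = np.asarray(included, int)
    if len(auc_voxel) != len(included):
        raise ValueError("value / index length mismatch")
    full = np.zeros(n_voxels)
    full[included] = auc_voxel
    chance_map = np.zeros(n_voxels)
    chance_map[included] = chance
    return full, chance_map


def group_test_vs_chance(
    values: np.ndarray,
    chance: float,
    domain: cluster_stats.ClusterDomain,
    n_permutations: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    alpha_element: float = 0.05,
) -> tuple[np.ndarray, ClusterReport]:
    """Cluster permutation test of per-subject AUC maps/curves vs chance.

    ``values`` is (n_subjects, n_locations[, n_times]); element statistic
    is the signed Wilcoxon rank sum against ``chance`` with subject
    sign-flip permutations.
    """
    values = np.asarray(values, float)
    if values.shape[0] < 5:
        raise ValueError("group test needs >= 5 subjects")
    report = cluster_stats.permutation_cluster_test(
        values - chance,
        domain,
        n_permutations=n_permutations,
        seed=seed,
        alpha=alpha,
        alpha_element=alpha_element,
        stat="wilcoxon",
    )
    mask = cluster_stats.sig_element_mask(report, domain.n_locations, domain.n_times)
    return np.squeeze(mask), report


@dataclass(frozen=True)
class GeneralizationSummary:
    mean_duration_ms: float
    frac_significant: float
    mean_auc_significant: float


def generalization_duration(
    sig_mask: np.ndarray,
    times: np.ndarray,
    auc_gen: Optional[np.ndarray] = None,
) -> GeneralizationSummary:
    """Average duration of significant generalization around the diagonal.

    For each training time, the length (ms) of the contiguous significant
    test-time run containing the diagonal element (0 if the diagonal is
    not significant); the summary value is the mean over training times.
    Also reports the fraction of significant cells and their mean AUC.
    """
    m = np.asarray(sig_mask, bool)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("mask must be square (train x test)")
    T = m.shape[0]
    dt_ms = float(np.mean(np.diff(times))) * 1000.0 if T > 1 else 0.0
    durations = np.zeros(T)
    for i in range(T):
        if not m[i, i]:
            continue
        lo = i
        while lo > 0 and m[i, lo - 1]:
            lo -= 1
        hi = i
        while hi < T - 1 and m[i, hi + 1]:
            hi += 1
        durations[i] = (hi - lo + 1) * dt_ms
    frac = float(m.mean())
    mean_auc = float(np.mean(auc_gen[m])) if (auc_gen is not None and m.any()) else float("nan")
    return GeneralizationSummary(
        mean_duration_ms=float(durations.mean()),
        frac_significant=frac,
        mean_auc_significant=mean_auc,
    )
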