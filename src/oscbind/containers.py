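"""Shared in-memory containers for the analysis pipeline.

Conventions used throughout the package:

* epoched sensor data are ``(n_trials, n_channels, n_times)`` float arrays in µV,
  with time 0 at stimulus onset;
* source-level data are ``(n_trials, n_voxels, n_times)``;
* condition labels are the strings ``go_nonoverlap``, ``go_overlap``,
  ``nogo_nonoverlap``, ``nogo_overlap``;
* the "binding" contrast is always overlapping minus non-overlapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

CONDITIONS = ("go_nonoverlap", "go_overlap", "nogo_nonoverlap", "nogo_overlap")
NOGO_CONDITIONS = ("nogo_nonoverlap", "nogo_overlap")
GO_CONDITIONS = ("go_nonoverlap", "go_overlap")

THETA_BAND = (4.0, 7.0)
ALPHA_BAND = (8.0, 12.0)


@dataclass(frozen=True)
class TaskDesign:
    """Go/Nogo task layout.

    Defaults are the full-scale session: 196 Go and 84 Nogo trials per
    overlap condition (70:30 Go:Nogo), seven equal blocks, 450 ms stimuli,
    a 1700 ms response window and 700-1100 ms uniformly jittered ITIs.
    """

    n_go_per_condition: int = 196
    n_nogo_per_condition: int = 84
    n_blocks: int = 7
    stim_duration_ms: float = 450.0
    response_window_ms: float = 1700.0
    iti_range_ms: tuple[float, float] = (700.0, 1100.0)

    def __post_init__(self) -> None:
        if self.n_go_per_condition < 1 or self.n_nogo_per_condition < 1:
            raise ValueError("need at least one trial per condition")
        if self.iti_range_ms[0] > self.iti_range_ms[1]:
            raise ValueError("iti_range min must not exceed max")
        if self.n_trials_total % self.n_blocks:
            raise ValueError(
                f"total trial count {self.n_trials_total} not divisible by "
                f"{self.n_blocks} blocks"
            )
        per_block = (self.n_go_per_condition % self.n_blocks == 0) and (
            self.n_nogo_per_condition % self.n_blocks == 0
        )
        if not per_block:
            raise ValueError("per-condition counts must divide evenly into blocks")

    @property
    def n_trials_total(self) -> int:
        return 2 * (self.n_go_per_condition + self.n_nogo_per_condition)

    @classmethod
    def scaled(cls, n_nogo: int = 40, n_blocks: int = 1) -> "TaskDesign":
        """Scaled-down design for fast simulation runs.

        Keeps the 70:30 Go:Nogo ratio (Go = 7/3 of Nogo, rounded to an
        integer) and all timing parameters of the full design.
        """
        n_go = int(round(n_nogo * 7 / 3))
        return cls(
            n_go_per_condition=n_go, n_nogo_per_condition=n_nogo, n_blocks=n_blocks
        )


@dataclass(frozen=True)
class TrialEvent:
    block_index: int
    onset_ms: float
    condition: str
    stimulus_id: str
    responded: bool = False
    rt_ms: Optional[float] = None

    def __post_init__(self) -> None:
        if self.responded != (self.rt_ms is not None):
            raise ValueError("rt present iff responded")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")


@dataclass(frozen=True)
class GroundTruth:
    """Planted effect description for the synthetic EEG generator.

    Each frequency band carries two planted components at its effect voxels:

    * a uniform band-power shift whose sign is ``theta_effect_sign`` (+1:
      overlapping > non-overlapping) resp. ``alpha_effect_sign`` (-1), with a
      Gaussian temporal envelope centred at the band's peak latency — this is
      what sensor-level cluster statistics and peak-latency analysis see;
    * a zero-mean discriminative voxel pattern (half the voxels up, half
      down per condition) that carries multivariate condition information.
      With ``shared_pattern`` the alpha pattern (and voxel set) equals the
      theta one, enabling theta-to-alpha transfer decoding; otherwise the
      alpha effect lives on a disjoint voxel set, making the two bands'
      condition-difference patterns orthogonal.
    """

    theta_effect_voxels: tuple[int, ...] = ()
    alpha_effect_voxels: tuple[int, ...] = ()
    theta_peak_latency_s: float = 0.52
    alpha_peak_latency_s: float = 0.59
    theta_effect_sign: int = 1
    alpha_effect_sign: int = -1
    shared_pattern: bool = True
    effect_amplitude: float = 1.0
    pattern_amplitude: Optional[float] = None  # default: 8 x effect_amplitude
    envelope_sd_s: float = 0.15
    behavioral_binding_fa: float = 35.3
    #: broad voxel set carrying only the uniform band-power shift (the
    #: spatially extended univariate effect the sensor statistics see);
    #: the theta/alpha effect voxels above carry the discriminative pattern
    power_shift_voxels: tuple[int, ...] = ()
    power_shift_base: float = 0.2

    def __post_init__(self) -> None:
        if self.effect_amplitude < 0:
            raise ValueError("effect_amplitude must be >= 0")
        if self.theta_effect_sign not in (1, -1) or self.alpha_effect_sign not in (1, -1):
            raise ValueError("effect signs must be +/-1")
        if self.shared_pattern and self.alpha_effect_voxels and (
            tuple(self.alpha_effect_voxels) != tuple(self.theta_effect_voxels)
        ):
            raise ValueError("shared_pattern requires identical effect voxel sets")

    @property
    def pattern_amp(self) -> float:
        """Amplitude of the discriminative pattern component.

        Defaults to 8 x the uniform power-shift amplitude: the pattern
        carries the representational (multivariate) content while the
        uniform shift is the weaker, spatially broad univariate band-power
        effect, so that cross-band transfer generalizes positively despite
        the bands' opposite-signed power shifts.  A zero effect amplitude
        therefore nulls both components (exchangeable conditions).
        """
        if self.pattern_amplitude is not None:
            return self.pattern_amplitude
        return 8.0 * self.effect_amplitude


@dataclass
class SensorEpochs:
    """Per-subject epoched sensor data (µV)."""

    data: np.ndarray  # (n_trials, n_channels, n_times)
    sfreq: float
    times: np.ndarray  # (n_times,) seconds, 0 = stimulus onset
    channel_positions: np.ndarray  # (n_channels, 3) cm
    condition_labels: np.ndarray  # (n_trials,) str
    subject_id: str = "S00"
    responded_before_ms: Optional[np.ndarray] = None  # per-trial response latency or nan

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.condition_labels = np.asarray(self.condition_labels)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, times)")
        if len(self.times) != self.data.shape[2]:
            raise ValueError("times length mismatch")
        if len(self.condition_labels) != self.data.shape[0]:
            raise ValueError("labels length mismatch")
        dt = np.diff(self.times)
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, 1.0 / self.sfreq, rtol=1e-3)):
            raise ValueError("times must increase uniformly at 1/sfreq")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def copy_with(self, **kw) -> "SensorEpochs":
        out = SensorEpochs(
            data=kw.get("data", self.data).copy(),
            sfreq=kw.get("sfreq", self.sfreq),
            times=kw.get("times", self.times).copy(),
            channel_positions=self.channel_positions,
            condition_labels=kw.get("condition_labels", self.condition_labels).copy(),
            subject_id=self.subject_id,
            responded_before_ms=kw.get("responded_before_ms", self.responded_before_ms),
        )
        return out


@dataclass
class LeadField:
    """Forward gain matrix on a regular voxel grid.

    ``gain`` maps a unit dipole moment along each of three orthogonal
    orientations at each voxel to sensor amplitudes:
    shape (n_channels, n_voxels, 3).  ``labels`` holds an atlas label per
    voxel; the sentinel labels ``unlabeled`` and ``cerebellar`` mark voxels
    excluded from source analysis.
    """

    gain: np.ndarray
    grid_coords: np.ndarray  # (n_voxels, 3) cm
    grid_spacing: float  # cm
    labels: np.ndarray  # (n_voxels,) str
    channel_positions: np.ndarray  # (n_channels, 3) cm

    EXCLUDED = ("unlabeled", "cerebellar")

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("gain must be finite")
        if self.gain.shape[1] != len(self.grid_coords):
            raise ValueError("gain / grid size mismatch")

    @property
    def n_voxels(self) -> int:
        return self.gain.shape[1]

    @property
    def n_channels(self) -> int:
        return self.gain.shape[0]

    def included_voxels(self) -> np.ndarray:
        """Indices of labeled, non-cerebellar voxels."""
        mask = ~np.isin(self.labels, list(self.EXCLUDED))
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise ValueError("no voxels left after exclusion")
        return idx


@dataclass
class TFR:
    """Time-frequency power, (n_trials_or_1, n_locations, n_freqs, n_times)."""

    power: np.ndarray
    frequencies: np.ndarray
    times: np.ndarray
    sfreq: float
    morlet_width: float
    valid_mask: np.ndarray  # (n_freqs, n_times) bool, False where edge-contaminated

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")


@dataclass
class BandPowerCourse:
    """Band-averaged power, (n_trials_or_1, n_locations, n_times)."""

    power: np.ndarray
    band: tuple[float, float]
    times: np.ndarray
    sfreq: float
    valid_mask: np.ndarray  # (n_times,) bool
    n_trials_averaged: Optional[int] = None

    def time_window_mask(self, tmin: float, tmax: float, valid_only: bool = True) -> np.ndarray:
        m = (self.times >= tmin) & (self.times <= tmax)
        if valid_only:
            m &= self.valid_mask
        return m


@dataclass
class SpatialFilter:
    weights: np.ndarray  # (n_voxels, n_channels)
    orientations: np.ndarray  # (n_voxels, 3)
    regularization: float
    voxel_ok: np.ndarray  # (n_voxels,) bool; False where filter computation failed


@dataclass
class Cluster:
    members: np.ndarray  # (k, 2) [location, time] or (k,) location indices
    stat_sum: float
    p_cluster: float
    sign: int


@dataclass
class ClusterReport:
    clusters: list
    n_permutations: int
    alpha: float
    max_stat_distribution: Optional[np.ndarray] = None

    def significant(self, alpha: Optional[float] = None) -> list:
        a = self.alpha if alpha is None else alpha
        return [c for c in self.clusters if c.p_cluster < a]

    @property
    def any_significant(self) -> bool:
        return any(c.p_cluster < self.alpha for c in self.clusters)

    def largest(self) -> Optional[Cluster]:
        if not self.clusters:
            return None
        return max(self.clusters, key=lambda c: abs(c.stat_sum))


@dataclass(frozen=True)
class DecodingConfig:
    classifier: str = "l1_svm"
    c_param: float = 1.0
    n_folds: int = 5
    metric: str = "auc"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.c_param <= 0:
            raise ValueError("c_param must be > 0")
        if self.classifier != "l1_svm" or self.metric != "auc":
            raise ValueError("only the L1-SVM / AUC configuration is supported")


@dataclass
class DecodingResult:
    auc_time: Optional[np.ndarray] = None
    auc_gen: Optional[np.ndarray] = None
    auc_voxel: Optional[np.ndarray] = None
    times: Optional[np.ndarray] = None
    sig_mask: Optional[np.ndarray] = None
    chance: float = 0.5


@dataclass
class VoxelCluster:
    member_voxels: np.ndarray
    centroid: np.ndarray
    labels: dict  # atlas label -> member count
    mean_auc: float


@dataclass
class VoxelClusterSet:
    clusters: list
    eps: float
    min_neighbors: int
    percentile: float

    def top_cluster(self) -> Optional[VoxelCluster]:
        if not self.clusters:
            return None
        return max(self.clusters, key=lambda c: c.mean_auc)
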