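"""Offline preprocessing chain for epoched sensor EEG.

Fixed stage order: band-pass + notch filter -> resample -> average
reference -> condition selection / artifact rejection -> baseline
correction.  Filters are zero-phase (forward-backward) Butterworth IIR so
that filtering cannot bias peak-latency estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
from scipy import signal
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .containers import SensorEpochs


@dataclass(frozen=True)
class RejectionPolicy:
    """Amplitude-based artifact criteria.

    ``amp_limit``: reject a trial if any sample exceeds +/- this value (µV).
    ``flat_limit`` / ``flat_window_ms``: reject if the peak-to-peak range
    within any sliding window of ``flat_window_ms`` stays below
    ``flat_limit`` (flat-line detection).
    """

    amp_limit: float = 200.0
    flat_limit: float = 0.5
    flat_window_ms: float = 100.0

    def __post_init__(self) -> None:
        if not (self.amp_limit > self.flat_limit >= 0):
            raise ValueError("need amp_limit > flat_limit >= 0")


def filter_array(
    data: np.ndarray,
    sfreq: float,
    low: float = 0.5,
    high: float = 40.0,
    notch: Optional[float] = 50.0,
    order: int = 4,
    notch_q: float = 30.0,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass plus IIR notch along the last axis."""
    nyq = sfreq / 2.0
    if not (0 < low < high):
        raise ValueError("need 0 < low < high")
    if high >= nyq:
        raise ValueError(f"high edge {high} Hz at or above Nyquist {nyq} Hz")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=sfreq, output="sos")
    out = signal.sosfiltfilt(sos, data, axis=-1)
    if notch is not None and notch < nyq:
        b, a = signal.iirnotch(notch, notch_q, fs=sfreq)
        out = signal.filtfilt(b, a, out, axis=-1)
    return out


def bandpass_and_notch(
    epochs: SensorEpochs,
    low: float = 0.5,
    high: float = 40.0,
    notch: Optional[float] = 50.0,
    order: int = 4,
) -> SensorEpochs:
    data = filter_array(epochs.data, epochs.sfreq, low, high, notch, order)
    return epochs.copy_with(data=data)


def resample(epochs: SensorEpochs, target_sfreq: float) -> SensorEpochs:
    """Polyphase anti-aliased resampling (e.g. 500 -> 256 Hz)."""
    if np.isclose(target_sfreq, epochs.sfreq):
        return epochs.copy_with()
    if target_sfreq > epochs.sfreq:
        raise ValueError("only downsampling is supported")
    frac = Fraction(target_sfreq / epochs.sfreq).limit_denominator(1000)
    data = signal.resample_poly(epochs.data, frac.numerator, frac.denominator, axis=-1)
    n_new = data.shape[-1]
    times = epochs.times[0] + np.arange(n_new) / target_sfreq
    return SensorEpochs(
        data=data,
        sfreq=target_sfreq,
        times=times,
        channel_positions=epochs.channel_positions,
        condition_labels=epochs.condition_labels.copy(),
        subject_id=epochs.subject_id,
        responded_before_ms=epochs.responded_before_ms,
    )


def rereference_average(epochs: SensorEpochs) -> SensorEpochs:
    if epochs.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    data = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    return epochs.copy_with(data=data)


def _flat_mask(data: np.ndarray, sfreq: float, policy: RejectionPolicy) -> np.ndarray:
    """Per-trial flag: peak-to-peak < flat_limit within some full window."""
    if policy.flat_limit <= 0:
        return np.zeros(data.shape[0], dtype=bool)
    w = int(round(policy.flat_window_ms / 1000.0 * sfreq))
    if w < 2 or w > data.shape[-1]:
        return np.zeros(data.shape[0], dtype=bool)
    # trailing windows [i-w+1, i]; only positions i >= w-1 are complete
    mx = maximum_filter1d(data, size=w, axis=-1, origin=-(w // 2) + (w - 1) // 2)
    mn = minimum_filter1d(data, size=w, axis=-1, origin=-(w // 2) + (w - 1) // 2)
    ptp = (mx - mn)[..., w - 1 :]
    return np.any(ptp < policy.flat_limit, axis=(1, 2))


def select_and_reject(
    epochs: SensorEpochs,
    policy: RejectionPolicy,
    conditions: Sequence[str],
    response_cutoff_ms: float = 1500.0,
) -> tuple[SensorEpochs, dict]:
    """Keep correctly-withheld trials of the requested conditions.

    Drops, in order: trials outside ``conditions``; trials with a response
    before ``response_cutoff_ms``; trials breaching the amplitude limit;
    trials with a flat segment.  Returns the surviving epochs plus a count
    log per rule.
    """
    labels = epochs.condition_labels.astype(str)
    keep_cond = np.isin(labels, list(conditions))
    counts = {"total": epochs.n_trials, "wrong_condition": int((~keep_cond).sum())}

    responded = np.zeros(epochs.n_trials, dtype=bool)
    if epochs.responded_before_ms is not None:
        rb = np.asarray(epochs.responded_before_ms, dtype=float)
        responded = np.isfinite(rb) & (rb < response_cutoff_ms)
    counts["responded"] = int((keep_cond & responded).sum())
    keep = keep_cond & ~responded

    amp_bad = np.any(np.abs(epochs.data) > policy.amp_limit, axis=(1, 2))
    counts["amplitude"] = int((keep & amp_bad).sum())
    keep &= ~amp_bad

    flat_bad = _flat_mask(epochs.data, epochs.sfreq, policy)
    counts["flat"] = int((keep & flat_bad).sum())
    keep &= ~flat_bad

    counts["retained"] = int(keep.sum())
    if counts["retained"] == 0:
        raise ValueError(f"all trials rejected (log: {counts})")
    out = SensorEpochs(
        data=epochs.data[keep],
        sfreq=epochs.sfreq,
        times=epochs.times.copy(),
        channel_positions=epochs.channel_positions,
        condition_labels=labels[keep],
        subject_id=epochs.subject_id,
        responded_before_ms=None
        if epochs.responded_before_ms is None
        else np.asarray(epochs.responded_before_ms)[keep],
    )
    return out, counts


def baseline_correct(
    epochs: SensorEpochs, window_ms: tuple[float, float] = (-200.0, 0.0)
) -> SensorEpochs:
    """Subtract the per-trial/channel mean over the baseline window."""
    t_ms = epochs.times * 1000.0
    mask = (t_ms >= window_ms[0]) & (t_ms < window_ms[1])
    if not np.any(mask):
        raise ValueError(f"baseline window {window_ms} ms outside the epoch")
    base = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return epochs.copy_with(data=epochs.data - base)
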