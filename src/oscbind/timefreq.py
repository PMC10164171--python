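"""Morlet wavelet time-frequency decomposition and band-power extraction.

The decomposition uses complex Morlet wavelets with a fixed number of
cycles (default m = 5, i.e. temporal sd sigma_t = m / (2 pi f)).  Power is
the squared magnitude of the wavelet convolution.  Samples within 3
sigma_t of either epoch edge are marked invalid for each frequency and are
excluded from downstream statistics and peak searches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from mne.time_frequency import tfr_array_morlet
from mne.time_frequency.tfr import morlet as make_morlet_wavelets

from .containers import BandPowerCourse, SensorEpochs, TFR

MORLET_WIDTH = 5.0
EDGE_SD_MARGIN = 3.0


def wavelet_temporal_sd(freq: float, width: float = MORLET_WIDTH) -> float:
    """Temporal standard deviation of an m-cycle Morlet wavelet (seconds)."""
    return width / (2.0 * np.pi * freq)


def source_frequency_grid(
    fmin: float = 2.0, fmax: float = 15.0, step: float = 0.5
) -> np.ndarray:
    """Frequency bins for source-level decomposition (2-15 Hz in 0.5 steps)."""
    n = int(round((fmax - fmin) / step)) + 1
    return fmin + step * np.arange(n)


def _strided_morlet_power(
    data2d: np.ndarray, wavelets: list, n_times: int, decim: int
) -> np.ndarray:
    """Power of the 'same'-mode wavelet convolution at every decim-th sample.

    One real GEMM per (real, imag) part against a stacked matrix of shifted
    wavelets; exact agreement with the FFT convolution at the evaluated
    samples, much cheaper when only a subsampled course is needed.
    """
    out_idx = np.arange(0, n_times, decim)
    mats = []
    for w in wavelets:
        L = len(w)
        s = (L - 1) // 2
        M = np.zeros((len(out_idx), n_times), dtype=complex)
        for row, j in enumerate(out_idx):
            k = j + s - np.arange(n_times)  # wavelet index per data sample
            ok = (k >= 0) & (k < L)
            M[row, ok] = w[k[ok]]
        mats.append(M)
    K = np.concatenate(mats, axis=0)  # (n_freqs*n_out, n_times)
    re = data2d @ K.real.T
    im = data2d @ K.imag.T
    power = re**2 + im**2
    return power.reshape(data2d.shape[0], len(wavelets), len(out_idx))


def morlet_tfr(
    data: Union[SensorEpochs, np.ndarray],
    frequencies: np.ndarray,
    width: float = MORLET_WIDTH,
    sfreq: Optional[float] = None,
    times: Optional[np.ndarray] = None,
    decim: int = 1,
) -> TFR:
    """Single-trial Morlet power.

    ``data`` may be a :class:`SensorEpochs` or a plain
    ``(n_trials, n_locations, n_times)`` array (then ``sfreq`` and
    ``times`` are required; this is how source-level courses are
    decomposed).  With ``decim`` > 1 the (smooth) power is evaluated only
    at every decim-th sample, which is dramatically cheaper for
    voxel-level decompositions.
    """
    if isinstance(data, SensorEpochs):
        arr, sfreq, times = data.data, data.sfreq, data.times
    else:
        arr = np.asarray(data, dtype=float)
        if sfreq is None or times is None:
            raise ValueError("sfreq and times required for array input")
    frequencies = np.asarray(frequencies, dtype=float)
    if np.any(frequencies >= sfreq / 2.0):
        raise ValueError("frequencies must be below Nyquist")
    n_times = arr.shape[-1]
    longest = 2 * 5 * wavelet_temporal_sd(frequencies.min(), width) * sfreq
    if longest > n_times:
        raise ValueError(
            f"epoch too short for a {width}-cycle wavelet at "
            f"{frequencies.min()} Hz ({longest:.0f} > {n_times} samples)"
        )
    if decim > 1:
        wavelets = make_morlet_wavelets(
            sfreq, frequencies, n_cycles=width, zero_mean=True
        )
        flat = arr.reshape(-1, n_times)
        power = _strided_morlet_power(flat, wavelets, n_times, decim)
        power = power.reshape(*arr.shape[:-1], len(frequencies), -1)
        out_times = np.asarray(times, float)[::decim]
        out_sfreq = sfreq / decim
    else:
        power = tfr_array_morlet(
            arr,
            sfreq=sfreq,
            freqs=frequencies,
            n_cycles=width,
            zero_mean=True,
            output="power",
            verbose="error",
        )
        out_times = np.asarray(times, dtype=float)
        out_sfreq = sfreq
    valid = np.ones((len(frequencies), n_times), dtype=bool)
    for i, f in enumerate(frequencies):
        margin = int(np.ceil(EDGE_SD_MARGIN * wavelet_temporal_sd(f, width) * sfreq))
        if margin > 0:
            valid[i, :margin] = False
            if margin < n_times:
                valid[i, -margin:] = False
            else:
                valid[i, :] = False
    valid = valid[:, ::decim] if decim > 1 else valid
    return TFR(
        power=power,
        frequencies=frequencies,
        times=out_times,
        sfreq=out_sfreq,
        morlet_width=width,
        valid_mask=valid,
    )


def band_power(tfr: TFR, band: tuple[float, float]) -> BandPowerCourse:
    """Mean power over frequency bins with centres in [low, high] inclusive."""
    lo, hi = band
    sel = (tfr.frequencies >= lo) & (tfr.frequencies <= hi)
    if not np.any(sel):
        raise ValueError(f"no frequency bins inside band {band}")
    power = tfr.power[:, :, sel, :].mean(axis=2)
    valid = np.all(tfr.valid_mask[sel], axis=0)
    return BandPowerCourse(
        power=power, band=(lo, hi), times=tfr.times, sfreq=tfr.sfreq, valid_mask=valid
    )


def condition_average(
    course: BandPowerCourse, labels: np.ndarray, condition: str
) -> BandPowerCourse:
    """Average the trial dimension over trials of one condition."""
    sel = np.asarray(labels).astype(str) == condition
    n = int(sel.sum())
    if n == 0:
        raise ValueError(f"no trials with condition {condition!r}")
    power = course.power[sel].mean(axis=0, keepdims=True)
    return BandPowerCourse(
        power=power,
        band=course.band,
        times=course.times,
        sfreq=course.sfreq,
        valid_mask=course.valid_mask.copy(),
        n_trials_averaged=n,
    )


def decimate_course(course: BandPowerCourse, factor: int) -> BandPowerCourse:
    """Subsample the (smooth) power course in time by an integer factor."""
    if factor <= 1:
        return course
    return BandPowerCourse(
        power=course.power[..., ::factor],
        band=course.band,
        times=course.times[::factor],
        sfreq=course.sfreq / factor,
        valid_mask=course.valid_mask[::factor],
        n_trials_averaged=course.n_trials_averaged,
    )


@dataclass(frozen=True)
class PeakLatency:
    time_s: float
    is_boundary: bool = False
    is_degenerate: bool = False


def peak_latency(
    course: Union[BandPowerCourse, np.ndarray],
    window: tuple[float, float] = (0.0, 1.0),
    times: Optional[np.ndarray] = None,
    valid_mask: Optional[np.ndarray] = None,
) -> PeakLatency:
    """Time of the largest local maximum of a subject-level course.

    Accepts a single-trial :class:`BandPowerCourse` (trial and location
    dimensions of size one, or pre-averaged) or a 1-D array plus ``times``.
    Edge-invalid samples are excluded.  If no interior local maximum exists
    the window argmax is returned with ``is_boundary`` set; an all-constant
    course is flagged degenerate.
    """
    if isinstance(course, BandPowerCourse):
        y = np.squeeze(course.power)
        times = course.times
        valid_mask = course.valid_mask
    else:
        y = np.squeeze(np.asarray(course, dtype=float))
        if times is None:
            raise ValueError("times required for array input")
    if y.ndim != 1:
        raise ValueError("peak_latency expects a single time course")
    sel = (times >= window[0]) & (times <= window[1])
    if valid_mask is not None:
        sel &= valid_mask
    idx = np.flatnonzero(sel)
    if idx.size < 3:
        raise ValueError("window too small (or fully edge-contaminated)")
    yw = y[idx]
    if np.allclose(yw, yw[0]):
        return PeakLatency(time_s=float(times[idx[0]]), is_degenerate=True)
    interior = np.flatnonzero(
        (yw[1:-1] > yw[:-2]) & (yw[1:-1] >= yw[2:])
    ) + 1
    if interior.size:
        best = interior[np.argmax(yw[interior])]
        return PeakLatency(time_s=float(times[idx[best]]))
    return PeakLatency(time_s=float(times[idx[np.argmax(yw)]]), is_boundary=True)
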