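"""Synthetic Go/Nogo EEG with planted theta/alpha binding effects.

Generates the task design (70:30 Go/Nogo, seven equal blocks, 450 ms
stimuli, 700-1100 ms jittered ITIs), behavioral outcome tables with a
configurable false-alarm binding effect, a forward model (analytic
single-sphere dipole solution or a seeded random full-rank gain), and
multi-subject epoched sensor EEG in which the overlapping vs.
non-overlapping Nogo contrast carries:

* a theta-band (5.5 Hz carrier) power increase for overlapping trials with
  a Gaussian envelope centred at 0.52 s,
* an alpha-band (10 Hz carrier) power decrease for overlapping trials with
  an envelope centred at 0.59 s,
* a zero-mean discriminative voxel pattern, shared (or not) between the
  two bands, which is what cross-frequency transfer decoding can exploit.

Ground truth (effect voxels, latencies, signs, pattern geometry) is known
exactly, so every downstream stage is testable without real recordings.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import (
    GO_CONDITIONS,
    NOGO_CONDITIONS,
    GroundTruth,
    LeadField,
    SensorEpochs,
    TaskDesign,
    TrialEvent,
)

# theta carrier sits mid-band but away from the alpha wavelet passband
# (a 5-cycle wavelet at 8 Hz has sigma_f = 1.6 Hz; at 5 Hz the response is
# ~0.17 in amplitude, so theta leakage into alpha-band power stays small)
THETA_CARRIER_HZ = 5.0
ALPHA_CARRIER_HZ = 10.0

#: the six stimulus identities (letters x font colour)
STIMULI = {
    "go_nonoverlap": ("green_PRESS",),
    "nogo_nonoverlap": ("red_STOPP",),
    "go_overlap": ("white_DRUECK", "blue_XXXXX"),
    "nogo_overlap": ("blue_DRUECK", "white_XXXXX"),
}

#: behavioral population parameters (mean, sd) per condition; percentages / ms
BEHAVIOR_MEANS = {
    "go_hit_rate": {"nonoverlap": (99.3, 0.9), "overlap": (98.7, 1.4)},
    "go_rt_ms": {"nonoverlap": (439.0, 52.0), "overlap": (450.0, 54.0)},
    "nogo_fa_rate": {"nonoverlap": (2.2, 3.0), "overlap": (37.5, 17.1)},
}


def generate_task_events(design: TaskDesign, seed: int) -> list[TrialEvent]:
    """Pseudorandomized trial sequence, balanced within each block."""
    rng = np.random.default_rng(seed)
    go_pb = design.n_go_per_condition // design.n_blocks
    nogo_pb = design.n_nogo_per_condition // design.n_blocks
    events: list[TrialEvent] = []
    onset = 0.0
    for block in range(design.n_blocks):
        conds = (
            ["go_nonoverlap"] * go_pb
            + ["go_overlap"] * go_pb
            + ["nogo_nonoverlap"] * nogo_pb
            + ["nogo_overlap"] * nogo_pb
        )
        order = rng.permutation(len(conds))
        counters = {c: 0 for c in STIMULI}
        for i in order:
            cond = conds[i]
            ids = STIMULI[cond]
            stim = ids[counters[cond] % len(ids)]
            counters[cond] += 1
            events.append(
                TrialEvent(
                    block_index=block,
                    onset_ms=onset,
                    condition=cond,
                    stimulus_id=stim,
                )
            )
            iti = rng.uniform(*design.iti_range_ms)
            onset += design.response_window_ms + iti
    return events


def _truncated_normal(rng, mean, sd, lo, hi, size):
    x = rng.normal(mean, sd, size=size)
    return np.clip(x, lo, hi)


def simulate_behavior(
    design: TaskDesign,
    truth: GroundTruth,
    n_subjects: int,
    seed: int,
    rt_binding_ms: float = 11.0,
    hit_binding_pp: float = -0.6,
) -> pd.DataFrame:
    """Per-subject behavioral table (one row per subject x overlap condition).

    The overlapping Nogo false-alarm mean exceeds the non-overlapping one by
    ``truth.behavioral_binding_fa`` percentage points before clipping to
    [0, 100]; overlapping Go RTs are slower by ``rt_binding_ms`` on average.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    fa_non_mean, fa_non_sd = BEHAVIOR_MEANS["nogo_fa_rate"]["nonoverlap"]
    fa_ov_sd_full = BEHAVIOR_MEANS["nogo_fa_rate"]["overlap"][1]
    full_binding = (
        BEHAVIOR_MEANS["nogo_fa_rate"]["overlap"][0]
        - BEHAVIOR_MEANS["nogo_fa_rate"]["nonoverlap"][0]
    )
    # the overlap-condition spread scales with the planted binding effect,
    # so a zero effect leaves the two conditions distributionally identical
    frac = min(abs(truth.behavioral_binding_fa) / full_binding, 1.0)
    fa_ov_sd = fa_non_sd + (fa_ov_sd_full - fa_non_sd) * frac
    rows = []
    for cond in ("nonoverlap", "overlap"):
        hit_m, hit_sd = BEHAVIOR_MEANS["go_hit_rate"][cond]
        rt_m, rt_sd = BEHAVIOR_MEANS["go_rt_ms"][cond]
        if cond == "nonoverlap":
            fa_m, fa_sd = fa_non_mean, fa_non_sd
            rt_mean = rt_m
            hit_mean = hit_m
        else:
            fa_m, fa_sd = fa_non_mean + truth.behavioral_binding_fa, fa_ov_sd
            rt_mean = BEHAVIOR_MEANS["go_rt_ms"]["nonoverlap"][0] + rt_binding_ms
            hit_mean = BEHAVIOR_MEANS["go_hit_rate"]["nonoverlap"][0] + hit_binding_pp
        rows.append(
            pd.DataFrame(
                {
                    "subject": [f"S{i:03d}" for i in range(n_subjects)],
                    "condition": cond,
                    "go_hit_rate": _truncated_normal(rng, hit_mean, hit_sd, 0, 100, n_subjects),
                    "go_rt_ms": np.maximum(rng.normal(rt_mean, rt_sd, n_subjects), 1.0),
                    "nogo_fa_rate": _truncated_normal(rng, fa_m, fa_sd, 0, 100, n_subjects),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

SENSOR_RADIUS_CM = 10.0

#: synthetic atlas region names assigned by octant
_REGION_NAMES = (
    "frontal_sup",
    "sma",
    "frontal_mid",
    "precentral",
    "temporal_mid",
    "occipital_mid",
    "fusiform",
    "temporal_sup",
)


def sensor_positions(n_channels: int, radius: float = SENSOR_RADIUS_CM) -> np.ndarray:
    """Equidistant-ish montage: Fibonacci lattice on the upper hemisphere."""
    i = np.arange(n_channels)
    golden = (1 + 5**0.5) / 2
    z = 0.15 + 0.85 * (i + 0.5) / n_channels  # upper hemisphere band
    phi = 2 * np.pi * i / golden
    r_xy = np.sqrt(1 - z**2)
    pts = np.stack([r_xy * np.cos(phi), r_xy * np.sin(phi), z], axis=1)
    return radius * pts


def _sphere_potential(
    electrodes: np.ndarray, sources: np.ndarray, radius: float, n_terms: int = 60
) -> np.ndarray:
    """Surface potential of unit dipoles in a homogeneous conducting sphere.

    Legendre-series solution for a dipole at radius b < R observed at a
    surface electrode:  V = sum_n (b^(n-1)/R^(n+1)) *
    [ (2n+1) q_r P_n(cos g) + ((2n+1)/n) q_t P_n^1(cos g) ],
    where q_r / q_t are the radial / in-plane tangential moment components
    and P_n^1 = (1-x^2)^(1/2) P_n' (no Condon-Shortley phase).  The overall
    1/(4 pi sigma) factor is dropped (arbitrary units).

    Returns (n_electrodes, n_sources, 3) gain for unit x/y/z moments.
    """
    E = electrodes / radius  # unit vectors (on surface)
    n_e, n_s = len(electrodes), len(sources)
    gain = np.zeros((n_e, n_s, 3))
    b = np.linalg.norm(sources, axis=1)
    for s in range(n_s):
        bs = b[s]
        if bs < 1e-9 * radius:
            # dipole at the centre: only the n=1 term survives
            gain[:, s, :] = 3.0 * E / radius**2
            continue
        bhat = sources[s] / bs
        cosg = np.clip(E @ bhat, -1.0, 1.0)
        # tangential unit vector at each electrode, in the (bhat, e) plane
        t = E - cosg[:, None] * bhat[None, :]
        tn = np.linalg.norm(t, axis=1)
        sing = tn.copy()
        with np.errstate(invalid="ignore", divide="ignore"):
            that = np.where(tn[:, None] > 1e-12, t / np.maximum(tn, 1e-12)[:, None], 0.0)
        # Legendre recurrences for P_n(cosg) and derivative
        p_prev = np.ones_like(cosg)  # P_0
        p_cur = cosg.copy()  # P_1
        dp_prev = np.zeros_like(cosg)  # P_0'
        dp_cur = np.ones_like(cosg)  # P_1'
        vr = np.zeros_like(cosg)
        vt = np.zeros_like(cosg)
        ratio = bs / radius
        coef = 1.0 / radius**2  # b^(n-1)/R^(n+1) at n=1
        for n in range(1, n_terms + 1):
            vr += coef * (2 * n + 1) * p_cur
            vt += coef * ((2 * n + 1) / n) * sing * dp_cur
            # advance recurrences to n+1
            p_next = ((2 * n + 1) * cosg * p_cur - n * p_prev) / (n + 1)
            dp_next = ((2 * n + 1) * (p_cur + cosg * dp_cur) - n * dp_prev) / (n + 1)
            p_prev, p_cur = p_cur, p_next
            dp_prev, dp_cur = dp_cur, dp_next
            coef *= ratio  # -> b^n / R^(n+2)
            if coef * (2 * n + 3) < 1e-14 / radius**2:
                break
        # assemble vector gain: q_r along bhat, q_t along that
        gain[:, s, :] = vr[:, None] * bhat[None, :] + vt[:, None] * that
    return gain


def make_leadfield(
    n_channels: int,
    grid_shape: tuple[int, int, int],
    grid_spacing: float,
    model: str = "spherical",
    seed: int = 0,
    channel_positions: Optional[np.ndarray] = None,
) -> LeadField:
    """Forward gain on a regular lattice with a synthetic atlas.

    The lattice is centred at the origin inside a sphere of sensors.  The
    lowest z-plane is labeled ``cerebellar`` and lattice corners beyond the
    inscribed sphere are ``unlabeled``; the rest get octant region names,
    providing a deterministic excluded/included split for testing.
    """
    if n_channels < 2:
        raise ValueError("need at least 2 channels")
    nx, ny, nz = grid_shape
    if nx * ny * nz == 0:
        raise ValueError("grid must be non-empty")
    chans = (
        sensor_positions(n_channels)
        if channel_positions is None
        else np.asarray(channel_positions, dtype=float)
    )
    if len(chans) != n_channels:
        raise ValueError("channel position count mismatch")
    d = np.linalg.norm(chans[:, None] - chans[None, :], axis=2)
    if np.any(d[np.triu_indices(n_channels, 1)] < 1e-9):
        raise ValueError("degenerate geometry: coincident sensors")
    ax = [grid_spacing * (np.arange(n) - (n - 1) / 2.0) for n in grid_shape]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    coords = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    max_r = np.linalg.norm(coords, axis=1).max()
    if max_r >= SENSOR_RADIUS_CM:
        raise ValueError("grid extends beyond the sensor sphere")

    rng = np.random.default_rng(seed)
    if model == "spherical":
        gain = _sphere_potential(chans, coords, SENSOR_RADIUS_CM)
    elif model == "random_full_rank":
        gain = rng.standard_normal((n_channels, len(coords), 3))
    else:
        raise ValueError(f"unknown forward model {model!r}")

    labels = np.empty(len(coords), dtype=object)
    r_inscribed = grid_spacing * (min(grid_shape) - 1) / 2.0 * np.sqrt(3) * 0.99
    zmin = coords[:, 2].min()
    for v, c in enumerate(coords):
        if np.isclose(c[2], zmin):
            labels[v] = "cerebellar"
        elif np.linalg.norm(c) > r_inscribed:
            labels[v] = "unlabeled"
        else:
            octant = (c[0] >= 0) * 4 + (c[1] >= 0) * 2 + (c[2] >= 0) * 1
            labels[v] = _REGION_NAMES[octant]
    return LeadField(
        gain=gain,
        grid_coords=coords,
        grid_spacing=grid_spacing,
        labels=np.asarray(labels),
        channel_positions=chans,
    )


# ---------------------------------------------------------------------------
# ground truth helpers
# ---------------------------------------------------------------------------


def _lattice_block(grid_shape, x0, y0, z0, size=(2, 1, 1)) -> tuple[int, ...]:
    nx, ny, nz = grid_shape
    idx = []
    for ix in range(x0, x0 + size[0]):
        for iy in range(y0, y0 + size[1]):
            for iz in range(z0, z0 + size[2]):
                idx.append(ix * ny * nz + iy * nz + iz)
    return tuple(idx)


def default_ground_truth(
    grid_shape: tuple[int, int, int] = (6, 6, 6),
    shared_pattern: bool = True,
    effect_amplitude: float = 0.15,
    pattern_amplitude: Optional[float] = None,
    **kw,
) -> GroundTruth:
    """Planted effects on two well-separated two-voxel blocks.

    The first block carries the positive half of the discriminative
    pattern, the second the negative half.  The blocks are several grid
    steps apart so that the pattern survives beamformer leakage (a
    fine-grained alternating pattern within one blob would be averaged out
    by the point spread of a low-channel-count montage), and they are kept
    small so that the filter's own-voxel gain dominates the incoherent
    leakage from the other block.  With ``shared_pattern`` the alpha
    effect uses the same block pair; otherwise a disjoint pair at the
    other two corners, making the two bands' condition-difference
    patterns orthogonal (zero inner product).
    """
    nx, ny, nz = grid_shape
    if min(nx, ny) < 6 or nz < 5:
        raise ValueError("grid too small for separated effect blocks")
    # superficial plane: closest to the sensor cap, hence best resolved
    z0 = nz - 1
    size = (2, 2, 1)
    # the four corner quadrants of the superficial plane; theta uses one
    # diagonal pair, the orthogonal alpha configuration the other, so the
    # two bands' effect sites are always >= 3 grid steps apart
    block_pos = _lattice_block(grid_shape, 0, 0, z0, size)
    block_neg = _lattice_block(grid_shape, nx - 2, ny - 2, z0, size)
    theta_vox = block_pos + block_neg
    if shared_pattern:
        alpha_vox = theta_vox
    else:
        alpha_vox = _lattice_block(grid_shape, 0, ny - 2, z0, size) + _lattice_block(
            grid_shape, nx - 2, 0, z0, size
        )
        if set(alpha_vox) & set(theta_vox):
            raise ValueError("grid too small for disjoint effect blocks")
    # broad univariate power shift over everything above the (cerebellar)
    # bottom plane: the spatially extended effect the sensor stats see
    broad = tuple(
        ix * ny * nz + iy * nz + iz
        for ix in range(nx)
        for iy in range(ny)
        for iz in range(1, nz)
    )
    return GroundTruth(
        theta_effect_voxels=theta_vox,
        alpha_effect_voxels=alpha_vox,
        shared_pattern=shared_pattern,
        effect_amplitude=effect_amplitude,
        pattern_amplitude=pattern_amplitude,
        power_shift_voxels=broad,
        **kw,
    )


def _pattern_signs(n: int) -> np.ndarray:
    """Zero-mean +/-1 pattern: +1 on the first half, -1 on the second.

    Effect voxel tuples are ordered (positive block, negative block), so
    this assigns one sign per block."""
    p = np.ones(n)
    p[n // 2 :] = -1.0
    return p


def planted_difference_pattern(
    truth: GroundTruth, n_voxels: int, band: str
) -> np.ndarray:
    """Full-grid voxel weight vector of the planted condition difference.

    Combines the uniform signed power shift and the zero-mean discriminative
    pattern; units are amplitude differences (overlapping - non-overlapping).
    """
    w = np.zeros(n_voxels)
    if band == "theta":
        vox, sign = truth.theta_effect_voxels, truth.theta_effect_sign
    elif band == "alpha":
        vox, sign = truth.alpha_effect_voxels, truth.alpha_effect_sign
    else:
        raise ValueError(band)
    vox = np.asarray(vox, dtype=int)
    if vox.size:
        w[vox] = (
            sign * truth.effect_amplitude
            + _pattern_signs(vox.size) * truth.pattern_amp
        )
    broad = np.asarray(
        [v for v in truth.power_shift_voxels if v not in set(vox.tolist())], dtype=int
    )
    if broad.size:
        w[broad] = sign * truth.effect_amplitude
    return w


# ---------------------------------------------------------------------------
# subject-level EEG
# ---------------------------------------------------------------------------


def _band_params(truth: GroundTruth, band: str):
    if band == "theta":
        return (
            np.asarray(truth.theta_effect_voxels, dtype=int),
            truth.theta_effect_sign,
            truth.theta_peak_latency_s,
            THETA_CARRIER_HZ,
        )
    return (
        np.asarray(truth.alpha_effect_voxels, dtype=int),
        truth.alpha_effect_sign,
        truth.alpha_peak_latency_s,
        ALPHA_CARRIER_HZ,
    )


def simulate_subject_eeg(
    design: TaskDesign,
    truth: GroundTruth,
    leadfield: LeadField,
    noise_sd: float = 1.0,
    sfreq: float = 128.0,
    epoch_window: tuple[float, float] = (-2.0, 2.0),
    seed: int = 0,
    conditions: Sequence[str] = NOGO_CONDITIONS,
    n_trials_per_condition: Optional[int] = None,
    base_amplitude: float = 1.0,
    amp_jitter: float = 0.1,
    trial_gain_sd: float = 0.25,
    amplitude_scale: float = 10.0,
    subject_id: str = "S00",
) -> SensorEpochs:
    """Epoched sensor EEG for one subject with the planted band effects.

    Per trial and band, source amplitude at each effect voxel is
    ``base + (sign*effect + p_v*pattern)/2`` for overlapping and
    ``base - (...)/2`` for non-overlapping trials (clipped at zero), with
    per-voxel multiplicative jitter and a shared lognormal per-trial gain
    (``trial_gain_sd``, an arousal-like global excitability fluctuation
    common to all sources), a Gaussian temporal envelope at the band's
    peak latency and per-trial, per-voxel random carrier phases.  White
    Gaussian sensor noise of ``noise_sd`` (in the same internal units) is
    added, and the result is multiplied by ``amplitude_scale`` to land in
    a realistic EEG microvolt range (every downstream statistic is
    invariant to this global scale, but absolute-amplitude artifact
    criteria are not).
    """
    rng = np.random.default_rng(seed)
    for band in ("theta", "alpha"):
        vox, _, peak, _ = _band_params(truth, band)
        if vox.size and truth.effect_amplitude > 0:
            sd = truth.envelope_sd_s
            if peak - 2 * sd < epoch_window[0] or peak + 2 * sd > epoch_window[1]:
                raise ValueError(
                    f"epoch window {epoch_window} shorter than the {band} "
                    f"effect envelope (peak {peak} s, sd {sd} s)"
                )
        if np.any(vox >= leadfield.n_voxels):
            raise ValueError("effect voxels outside the grid")

    n_pc = (
        design.n_nogo_per_condition
        if n_trials_per_condition is None
        else n_trials_per_condition
    )
    labels = np.repeat(list(conditions), n_pc)
    rng.shuffle(labels)
    n_trials = len(labels)

    n_times = int(round((epoch_window[1] - epoch_window[0]) * sfreq))
    times = epoch_window[0] + np.arange(n_times) / sfreq

    # effective gain column per voxel with a fixed (radial-ish) orientation
    ori = leadfield.grid_coords.copy()
    norms = np.linalg.norm(ori, axis=1)
    ori[norms < 1e-9] = [0.0, 0.0, 1.0]
    ori /= np.linalg.norm(ori, axis=1, keepdims=True)
    gain_eff = np.einsum("cvo,vo->cv", leadfield.gain, ori)  # (C, V)

    data = rng.normal(0.0, noise_sd, size=(n_trials, leadfield.n_channels, n_times))
    overlap = np.char.endswith(labels.astype(str), "_overlap")
    cond_pm = np.where(overlap, 1.0, -1.0)
    trial_gain = np.exp(trial_gain_sd * rng.standard_normal(n_trials))

    for band in ("theta", "alpha"):
        vox_p, sign, peak, carrier = _band_params(truth, band)
        vox_b = np.asarray(
            [v for v in truth.power_shift_voxels if v not in set(vox_p.tolist())],
            dtype=int,
        )
        if vox_p.size == 0 and vox_b.size == 0:
            continue
        # pattern voxels: uniform shift + discriminative pattern;
        # broad voxels: uniform band-power shift only (weak but extended,
        # this is what sensor-level statistics pick up)
        p_v = _pattern_signs(vox_p.size)
        half = np.concatenate(
            [
                0.5 * (sign * truth.effect_amplitude + p_v * truth.pattern_amp),
                0.5 * sign * truth.effect_amplitude * np.ones(vox_b.size),
            ]
        )
        base = np.concatenate(
            [
                base_amplitude * np.ones(vox_p.size),
                truth.power_shift_base * np.ones(vox_b.size),
            ]
        )
        vox = np.concatenate([vox_p, vox_b])
        env = np.exp(-0.5 * ((times - peak) / truth.envelope_sd_s) ** 2)
        # independent carrier phase per trial AND per voxel: sources are
        # mutually incoherent, so beamformer leakage adds in power, not in
        # amplitude, and condition information stays local to the blocks
        phases = rng.uniform(0, 2 * np.pi, size=(n_trials, vox.size))
        jitter = 1.0 + amp_jitter * rng.standard_normal((n_trials, vox.size))
        amps = np.clip(
            (base[None, :] + cond_pm[:, None] * half[None, :])
            * jitter
            * trial_gain[:, None],
            0.0,
            None,
        )
        carrier_wave = env[None, None, :] * np.sin(
            2 * np.pi * carrier * times[None, None, :] + phases[:, :, None]
        )  # (T, V_eff, n_times)
        g = gain_eff[:, vox]  # (C, V_eff)
        src = amps[:, :, None] * carrier_wave  # (T, V_eff, n_times)
        data += np.einsum("cv,tvn->tcn", g, src)

    data *= amplitude_scale
    return SensorEpochs(
        data=data,
        sfreq=sfreq,
        times=times,
        channel_positions=leadfield.channel_positions,
        condition_labels=labels.astype(str),
        subject_id=subject_id,
        responded_before_ms=np.full(n_trials, np.nan),
    )
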