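"""Readers and writers.

The interchange format for synthetic recordings is an HDF5 container:

    /epochs             (trials, channels, times) float64, µV
    /labels             per-trial condition strings
    /sfreq              scalar Hz
    /times              (times,) seconds
    /channel_positions  (channels, 3) cm
    /responded_before_ms optional per-trial response latency (NaN = none)
    attrs: subject_id

Events and behavioral tables are TSV; cluster reports serialize to JSON.
Real recordings (BrainVision, EDF) are read through MNE.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .containers import ClusterReport, LeadField, SensorEpochs, TrialEvent


def save_epochs(path, epochs: SensorEpochs) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("epochs", data=epochs.data)
        f.create_dataset(
            "labels", data=np.asarray(epochs.condition_labels, dtype="S32")
        )
        f.create_dataset("sfreq", data=float(epochs.sfreq))
        f.create_dataset("times", data=epochs.times)
        f.create_dataset("channel_positions", data=epochs.channel_positions)
        if epochs.responded_before_ms is not None:
            f.create_dataset("responded_before_ms", data=epochs.responded_before_ms)
        f.attrs["subject_id"] = epochs.subject_id


def load_epochs(path) -> SensorEpochs:
    with h5py.File(path, "r") as f:
        return SensorEpochs(
            data=f["epochs"][()],
            sfreq=float(f["sfreq"][()]),
            times=f["times"][()],
            channel_positions=f["channel_positions"][()],
            condition_labels=f["labels"][()].astype(str),
            subject_id=str(f.attrs.get("subject_id", "S00")),
            responded_before_ms=f["responded_before_ms"][()]
            if "responded_before_ms" in f
            else None,
        )


def save_leadfield(path, lf: LeadField) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("gain", data=lf.gain)
        f.create_dataset("grid_coords", data=lf.grid_coords)
        f.create_dataset("grid_spacing", data=float(lf.grid_spacing))
        f.create_dataset("labels", data=np.asarray(lf.labels, dtype="S32"))
        f.create_dataset("channel_positions", data=lf.channel_positions)


def load_leadfield(path) -> LeadField:
    with h5py.File(path, "r") as f:
        return LeadField(
            gain=f["gain"][()],
            grid_coords=f["grid_coords"][()],
            grid_spacing=float(f["grid_spacing"][()]),
            labels=f["labels"][()].astype(str),
            channel_positions=f["channel_positions"][()],
        )


def events_to_tsv(events: Sequence[TrialEvent], path) -> None:
    pd.DataFrame(
        {
            "block_index": [e.block_index for e in events],
            "onset_ms": [e.onset_ms for e in events],
            "condition": [e.condition for e in events],
            "stimulus_id": [e.stimulus_id for e in events],
            "responded": [e.responded for e in events],
            "rt_ms": [e.rt_ms if e.rt_ms is not None else np.nan for e in events],
        }
    ).to_csv(path, sep="\t", index=False)


def cluster_report_to_json(report: ClusterReport, path=None) -> dict:
    obj = {
        "n_permutations": report.n_permutations,
        "alpha": report.alpha,
        "clusters": [
            {
                "stat_sum": c.stat_sum,
                "p_cluster": c.p_cluster,
                "sign": c.sign,
                "members": np.asarray(c.members).tolist(),
            }
            for c in report.clusters
        ],
    }
    if path is not None:
        Path(path).write_text(json.dumps(obj, indent=1))
    return obj


def read_brainvision(vhdr_path):
    """Raw BrainVision recording via MNE (real-data path)."""
    import mne

    return mne.io.read_raw_brainvision(vhdr_path, preload=True, verbose="error")


def read_edf(path):
    """Raw EDF recording via MNE (real-data path)."""
    import mne

    return mne.io.read_raw_edf(path, preload=True, verbose="error")


def epochs_from_raw(
    raw,
    onsets_s: np.ndarray,
    labels: Sequence[str],
    epoch_window: tuple[float, float],
    channel_positions=None,
    subject_id: str = "S00",
) -> SensorEpochs:
    """Cut an MNE Raw into the package's epoch container."""
    sfreq = float(raw.info["sfreq"])
    data = raw.get_data() * 1e6  # V -> µV
    n = int(round((epoch_window[1] - epoch_window[0]) * sfreq))
    segs = []
    for onset in onsets_s:
        start = int(round((onset + epoch_window[0]) * sfreq))
        if start < 0 or start + n > data.shape[1]:
            raise ValueError("epoch extends beyond the recording")
        segs.append(data[:, start : start + n])
    times = epoch_window[0] + np.arange(n) / sfreq
    if channel_positions is None:
        channel_positions = np.zeros((data.shape[0], 3))
    return SensorEpochs(
        data=np.stack(segs),
        sfreq=sfreq,
        times=times,
        channel_positions=channel_positions,
        condition_labels=np.asarray(labels),
        subject_id=subject_id,
    )
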