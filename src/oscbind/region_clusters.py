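"""DBSCAN localization of peak-decoding voxels.

The top percentile (default 2 %) of the AUC map over included (labeled,
non-cerebellar) voxels is clustered with DBSCAN at eps = 1.5 x the grid
spacing and min_samples = 2 ("at least one neighbor"), which makes the
clusters exactly the connected components of the eps-neighborhood graph;
isolated voxels are noise.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from .containers import LeadField, VoxelCluster, VoxelClusterSet


def top_percentile_mask(
    auc_map: np.ndarray,
    included: np.ndarray,
    percentile: float = 0.02,
) -> np.ndarray:
    """Indices of included voxels with AUC at or above the top-percentile cut.

    The quantile is computed over included voxels only (excluded positions
    carry the re-insertion value 0, which would distort it); ties at the
    threshold are all kept.
    """
    included = np.asarray(included, int)
    vals = np.asarray(auc_map, float)[included]
    if np.allclose(vals, vals[0]):
        raise ValueError("constant AUC map: no top percentile")
    if not (0 < percentile <= 1):
        raise ValueError("percentile must be in (0, 1]")
    thr = np.quantile(vals, 1.0 - percentile)
    mask = vals >= thr - 1e-12
    out = included[mask]
    if out.size == 0:
        raise ValueError("empty top-percentile set")
    return out


def dbscan_voxels(
    voxel_indices: np.ndarray,
    coords: np.ndarray,
    eps: float,
    min_pts: int = 2,
    auc_map: Optional[np.ndarray] = None,
    labels: Optional[np.ndarray] = None,
    percentile: float = 0.02,
) -> VoxelClusterSet:
    """Cluster candidate voxels by spatial density (Euclidean metric)."""
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if min_pts < 2:
        raise ValueError("min_pts must be >= 2")
    voxel_indices = np.asarray(voxel_indices, int)
    pts = np.asarray(coords, float)[voxel_indices]
    assignment = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(pts)
    clusters = []
    for cid in sorted(set(assignment) - {-1}):
        members = voxel_indices[assignment == cid]
        mean_auc = float(np.mean(auc_map[members])) if auc_map is not None else float("nan")
        lab_counts: dict = {}
        if labels is not None:
            for lab in np.asarray(labels)[members]:
                lab_counts[str(lab)] = lab_counts.get(str(lab), 0) + 1
        clusters.append(
            VoxelCluster(
                member_voxels=members,
                centroid=np.asarray(coords)[members].mean(axis=0),
                labels=lab_counts,
                mean_auc=mean_auc,
            )
        )
    return VoxelClusterSet(
        clusters=clusters, eps=float(eps), min_neighbors=min_pts - 1, percentile=percentile
    )


def find_decoding_clusters(
    auc_map: np.ndarray,
    leadfield: LeadField,
    included: np.ndarray,
    percentile: float = 0.02,
    eps_factor: float = 1.5,
    min_pts: int = 2,
) -> VoxelClusterSet:
    """Top-percentile mask + DBSCAN in one step."""
    top = top_percentile_mask(auc_map, included, percentile)
    return dbscan_voxels(
        top,
        leadfield.grid_coords,
        eps=eps_factor * leadfield.grid_spacing,
        min_pts=min_pts,
        auc_map=auc_map,
        labels=leadfield.labels,
        percentile=percentile,
    )


def summarize_clusters(cluster_set: VoxelClusterSet) -> pd.DataFrame:
    """Tabular report: one row per cluster, sorted by mean AUC."""
    rows = []
    for i, c in enumerate(
        sorted(cluster_set.clusters, key=lambda c: -c.mean_auc)
    ):
        rows.append(
            {
                "cluster_id": i,
                "n_voxels": len(c.member_voxels),
                "mean_auc": c.mean_auc,
                "centroid_x": c.centroid[0],
                "centroid_y": c.centroid[1],
                "centroid_z": c.centroid[2],
                "labels": ";".join(
                    f"{k}:{v}" for k, v in sorted(c.labels.items(), key=lambda kv: -kv[1])
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "n_voxels", "mean_auc",
            "centroid_x", "centroid_y", "centroid_z", "labels",
        ],
    )
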