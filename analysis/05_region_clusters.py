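#!/usr/bin/env python
"""Localize peak-decoding voxels: DBSCAN (eps = 1.5 x grid spacing,
min 2 points) on the top 2% of the group-mean AUC map of each
classification, restricted to labeled non-cerebellar voxels.
"""

import argparse
from pathlib import Path

import pandas as pd

from oscbind.pipeline import MODES, RunConfig, stage_clusters

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--out", type=Path, default=Path("results/run"))
args = parser.parse_args()

cfg = RunConfig.from_yaml(args.out / "config.yaml")
stage_clusters(cfg, args.out)
for mode in MODES:
    df = pd.read_csv(args.out / f"clusters_{mode}.tsv", sep="\t")
    if len(df) == 0:
        print(f"{mode}: no clusters")
        continue
    for _, row in df.iterrows():
        print(
            f"{mode} cluster {row.cluster_id}: {row.n_voxels} voxels, "
            f"mean AUC {row.mean_auc:.3f}, regions {row.labels}"
        )
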