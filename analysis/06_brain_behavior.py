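#!/usr/bin/env python
"""Brain-behavior link: Wilcoxon contrasts of the behavioral measures
(with Rosenthal's r), the false-alarm binding effect per subject, and a
backward-elimination regression of the binding effect onto the mean AUC
of each DBSCAN cluster.  Finishes by writing the run report.
"""

import argparse
import json
from pathlib import Path

from oscbind.pipeline import RunConfig, stage_regress, stage_report, report_text

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--out", type=Path, default=Path("results/run"))
args = parser.parse_args()

cfg = RunConfig.from_yaml(args.out / "config.yaml")
stage_regress(cfg, args.out)
stage_report(cfg, args.out)
reg = json.loads((args.out / "regression.json").read_text())
for var, res in reg["behavior_tests"].items():
    if "error" in res:
        print(f"{var}: {res['error']}")
    else:
        print(f"{var}: z = {res['z']:.2f}, p = {res['p']:.3g}, r = {res['r']:.3f}")
if "predictors_final" in reg:
    print(
        f"regression retained {reg['predictors_final']} "
        f"(adj R2 {reg['adjusted_r2']:.3f}, Durbin-Watson {reg['durbin_watson']:.2f})"
    )
print()
print(report_text(args.out))
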