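#!/usr/bin/env python
"""Preprocess the simulated recordings: optional band-pass/notch filter,
average reference, Nogo-trial selection with amplitude/flat-line artifact
rejection, and baseline correction.

Reads epochs_*.h5 from the run directory, writes prep_*.h5 plus a JSON
log of trial counts per rejection rule.
"""

import argparse
import json
from pathlib import Path

from oscbind.pipeline import RunConfig, stage_preprocess

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--out", type=Path, default=Path("results/run"))
args = parser.parse_args()

cfg = RunConfig.from_yaml(args.out / "config.yaml")
stage_preprocess(cfg, args.out)
counts = json.loads((args.out / "preprocess_counts.json").read_text())
total = sum(c["total"] for c in counts.values())
kept = sum(c["retained"] for c in counts.values())
print(f"preprocessed {len(counts)} subjects: kept {kept}/{total} trials")
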