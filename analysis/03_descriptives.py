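#!/usr/bin/env python
"""Cohort descriptives and compositional co-dependence.

Computes arithmetic means (raw minutes), the compositional geometric mean
closed to 1440 min with percentage shares, wellbeing domain means, and the
variation matrix of pairwise log-ratio variances (small = the two
behaviours co-vary tightly). Writes descriptives.json and
variation_matrix.csv under results/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from coda24.coda import CANONICAL_PARTS, close, variation_matrix
from coda24.pipeline import descriptives

parser = argparse.ArgumentParser()
parser.add_argument("--dataset", type=Path, default=Path("results/analysis_dataset.csv"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

df = pd.read_csv(args.dataset)
desc = descriptives(df)
comps = [close(r) for r in df[list(CANONICAL_PARTS)].to_numpy(float)]
vm = variation_matrix(comps)

args.out.mkdir(parents=True, exist_ok=True)
with open(args.out / "descriptives.json", "w") as fh:
    json.dump(desc, fh, indent=2, default=float)
pd.DataFrame(vm.entries, index=vm.labels, columns=vm.labels).to_csv(
    args.out / "variation_matrix.csv"
)

print(f"n = {desc['n']}")
print("behaviour  arith.mean  geo.mean  share%")
for p in CANONICAL_PARTS:
    print(
        f"{p:9s} {desc['arithmetic_mean_min'][p]:10.1f} "
        f"{desc['geometric_mean_min'][p]:9.1f} {desc['geometric_mean_pct'][p]:7.1f}"
    )
print("\npairwise log-ratio variances (ascending co-dependence rank):")
for a, b, v in vm.ordered_pairs():
    print(f"  var(ln {a}/{b}) = {v:.3f}")
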