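#!/usr/bin/env python
"""Scan the inhibitor off-rate and watch a competitive inhibitor change face.

Simulates the pre-incubated, substrate-initiated initial-velocity
experiment (Km 10 uM, kcat 1000 1/s, Ki fixed at 1 uM, 1e6 s pre-
incubation, 10 s dead time) across a log grid of k_off, runs the
conventional Lineweaver-Burk + Dixon/Cornish-Bowden analysis on each
dataset, and tabulates the apparent inhibition constants.

Expected outcome: the apparent competitive constant stays at the true
1 uM everywhere, while an apparent uncompetitive component emerges as the
residence time grows - competitive above k_off ~ 3e-2 1/s, apparently
mixed down to ~3e-4 1/s, apparently purely noncompetitive below.
"""

import argparse
from pathlib import Path

import numpy as np

from tdikin.steady_state import koff_scan

parser = argparse.ArgumentParser()
parser.add_argument("--out", type=Path, default=Path("results"))
parser.add_argument("--n-points", type=int, default=25)
args = parser.parse_args()

grid = np.logspace(-5, 3, args.n_points)
table = koff_scan(grid)
args.out.mkdir(parents=True, exist_ok=True)
table.to_csv(args.out / "koff_scan.csv", index=False)

print(table.to_string(index=False))
band = table[table["classification"] == "mixed"]["k_off_per_s"]
print(
    f"\nApparent mixed-type band: k_off in [{band.min():.1e}, {band.max():.1e}] 1/s "
    f"(true mechanism is purely competitive at every point)."
)
print(f"Wrote {args.out/'koff_scan.csv'}")
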