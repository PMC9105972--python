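#!/usr/bin/env python
"""How the order of reagent addition distorts the galantamine Ki.

Emulates the two Ellman-assay inhibition experiments on the TcAChE scheme
at the case-study constants (true Ki = 8.45 nM, kon = 1.9e6 1/(M s)):

* enzyme-initiated (no pre-incubation): the slow EI on-rate leaves the
  first seconds nearly uninhibited, so the conventional analysis sees a
  competitive pattern with a grossly overestimated Ki;
* substrate-initiated after 20 min pre-incubation: slow EI dissociation
  makes the curves sweep upward and the analysis reports an apparent
  mixed/noncompetitive pattern near the true Ki.

Writes the velocity tables and apparent constants under results/.
"""

import argparse
import json
from pathlib import Path

from tdikin.assays import gal_design, generate_curves, tcache_reference_rates
from tdikin.mechanisms import build_scheme
from tdikin.steady_state import analyze_inhibition, velocity_dataset

parser = argparse.ArgumentParser()
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

mech = build_scheme("slyke_cullen_product_inhibitor")
rates = tcache_reference_rates()
true_ki = rates.ki()

summary = {"true_Ki_nM": true_ki * 1e9}
for variant in ("enzyme_initiated", "substrate_initiated"):
    design = gal_design(variant)
    curves = generate_curves(design, mech, rates)
    vds = velocity_dataset(curves, design.dead_time_s, design.velocity_window_s)
    res = analyze_inhibition(vds)
    vds.to_csv(args.out / f"velocities_{variant}.csv", index=False)
    summary[variant] = res.to_dict()
    kiu = "absent" if res.K_iu == float("inf") else f"{res.K_iu*1e9:.1f} nM"
    print(
        f"{variant:20s}: apparent Kic = {res.K_ic*1e9:6.1f} nM, Kiu = {kiu:>10s} "
        f"-> looks {res.classification} (true: competitive, Ki = {true_ki*1e9:.2f} nM)"
    )

with open(args.out / "initiation_order.json", "w") as fh:
    json.dump(summary, fh, indent=2)
print(f"Wrote {args.out/'initiation_order.json'}")
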