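"""Simulate the ectopic-expression + PDBu protocol and print the readouts.

Builds the shuttle variant (A) at its reference parameterization, integrates
it through protocol E2 (PI4KIIIbeta expressed from transfection at 0 h, PKD
activated with PDBu at 24 h) and prints the blot observables: total
PI4KIIIbeta at 24 h and the phospho-PKD / phospho-PI4KIIIbeta time courses
in the hour after activation.
"""

import numpy as np

import tgnkin as tk
from tgnkin.models import build_model, steady_state
from tgnkin.protocols import simulate
from tgnkin.synth import default_protocols

model = build_model("A")
params = tk.ground_truth("A")
proto = {p.pid: p for p in default_protocols()}["E2"]

rest = steady_state(model, params)
print("endogenous steady state (molecules/cell):")
for name, value in zip(model.species_names, rest):
    print(f"  {name:10s} {value:12.0f}")

traj = simulate(model, params, proto)
times = [24.0, 24 + 1 / 6, 24 + 1 / 3, 24.5, 25.0]
print(f"\nPI4K total at 24 h: {traj.series('PI4K_total', [24.0])[0]:.3g} "
      "molecules/cell (ectopic expression on top of ~2e6 endogenous)")
print("time after PDBu [min] |  phospho-PKD  |  phospho-PI4K")
for t, ppkd, ppi4k in zip(times, traj.series("pPKD", times),
                          traj.series("pPI4K", times)):
    print(f"  {60 * (t - 24):5.0f}               | {ppkd:12.3g} | {ppi4k:12.3g}")
print("\nPDBu drives active PKD up more than tenfold within the hour, with "
      "phospho-PI4K following - the activation cascade the time-series "
      "experiments measure.")
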