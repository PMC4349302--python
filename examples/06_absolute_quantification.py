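"""Absolute protein abundance from a recombinant-standard blot.

Mirrors the quantification workflow: fit a standard curve to a dilution
series of recombinant protein, invert it to get the ectopically expressed
molecule count from its band intensity, then scale by the
endogenous/ectopic signal ratio to obtain molecules per cell with a
propagated coefficient of variation.
"""

import numpy as np

from tgnkin.quantify import (endogenous_abundance, fit_standard_curve,
                             inverse_predict)

rng = np.random.default_rng(4)
molecules = np.linspace(2e9, 5e10, 7)          # dilution series of standard
intensity = 1.2 + 1.8e-9 * molecules + rng.normal(0, 0.6, 7)
curve = fit_standard_curve(np.column_stack([molecules, intensity]))
print(f"standard curve: intensity = {curve.intercept:.2f} + "
      f"{curve.slope:.2e} x molecules  (residual SD {curve.residual_sd:.2f}, "
      f"n = {curve.n})")

band = 1.2 + 1.8e-9 * 2.4e10                   # intensity of the ectopic band
inv = inverse_predict(curve, band)
print(f"ectopic band -> {inv.molecules:.3g} +- {inv.se:.2g} molecules "
      f"in the lysate")

est = endogenous_abundance(ratio_endo_to_ectopic=0.083,
                           ectopic_molecules_in_lysate=inv.molecules,
                           n_cells=1e6,
                           cvs=(inv.se / inv.molecules, 0.25))
print(f"endogenous abundance: {est.molecules_per_cell:.3g} molecules/cell, "
      f"CV {100 * est.cv:.0f}%")
print("\nCVs in the 25-40% range pin the order of magnitude - exactly the "
      "precision absolute model calibration needs.")
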