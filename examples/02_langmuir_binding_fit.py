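"""Fit the hyperbolic (Langmuir) binding model to a titration.

Simulates a noisy coverage-vs-concentration titration at known Phi_max and
Kd, then fits it both with Phi_max fixed (the usual reporting convention)
and jointly free.
"""

import numpy as np

from guvkit.binding import fit_langmuir, predict_phi
from guvkit.synthetic import TitrationTruth, simulate_titration

truth = TitrationTruth(phi_max=12.0, kd=1.2,
                       concentrations_um=tuple(np.geomspace(0.02, 4.0, 8)),
                       noise_cv=0.10, seed=2)
table = simulate_titration(truth)
print(table.round(3).to_string(index=False))

fixed = fit_langmuir(table, fix_phi_max=12.0)
joint = fit_langmuir(table)
print(f"\ngenerating parameters: Phi_max = 12.0 %, Kd = 1.20 uM")
print(f"fixed-Phi_max fit:     Kd = {fixed.kd:.2f} uM")
print(f"joint fit:             Phi_max = {joint.phi_max:.1f} %, "
      f"Kd = {joint.kd:.2f} uM")
print(f"coverage predicted at 4 uM: {predict_phi(fixed, 4.0):.2f} %")
print()
print("Kd is the bulk concentration at half-saturating membrane coverage;")
print("a smaller Kd means higher membrane affinity.")
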