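"""Fit the equilibrium unfolding model to a single melting curve.

Builds a noise-free six-temperature series from known parameters, runs the
reference normalization and the nonlinear fit, and prints the recovered
parameters next to the truth.
"""

import numpy as np
import pandas as pd

from meltshift import fit_unfolding, fraction_folded, melting_point, normalize_to_reference

temps = np.array([43.0, 46.4, 49.8, 53.2, 56.6, 60.0])  # degC
a_true, b_true, p_true = -0.8, 51.0, 0.1

raw = pd.DataFrame(
    {
        "temperature_c": temps,
        "intensity": 2.5e6 * fraction_folded(temps, a_true, b_true, p_true),
        "replicate": 1,
    }
)
curve, _ = normalize_to_reference(raw, "EXAMPLE", "vehicle")
fit = fit_unfolding(curve)

print(f"true parameters:  a={a_true:.4f}  b={b_true:.4f}  p={p_true:.4f}")
print(f"fitted:           a={fit.a:.4f}  b={fit.b:.4f}  p={fit.p:.4f}")
print(f"melting point Tm: {fit.tm:.4f} degC "
      f"(closed form from truth: {melting_point(a_true, b_true, p_true):.4f})")
print(f"r^2 = {fit.r_squared:.6f}, converged = {fit.converged}")
# Tm is where the fitted fraction folded crosses 0.5: the temperature at
# which half of the protein is denatured. With plateau p > 0 it lies above
# the inflection b.
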