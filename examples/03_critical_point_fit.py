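"""Critical-point fitting of a coexistence curve.

Generates a synthetic dense/dilute coexistence curve from the scaling law
(order parameter exponent beta = 0.325 and the rectilinear diameter), adds
2% noise, and fits back the critical temperature Tc, amplitude B, critical
density rho_c, and diameter slope C.
"""

import numpy as np

from slabsim import fit_critical_point
from slabsim.synth import gen_coexistence_data

truth = dict(Tc=296.0, B=900.0, rho_c=310.0, C=2.5)
temps = np.linspace(240.0, 293.0, 10)

clean = gen_coexistence_data(**truth, temps=temps)
noisy = gen_coexistence_data(**truth, temps=temps, noise_rel=0.02, seed=1)

for label, curve in (("noiseless", clean), ("2% noise", noisy)):
    fit = fit_critical_point(curve)
    print(f"{label:9s}: Tc = {fit.Tc:7.2f} K  B = {fit.B:6.1f}  "
          f"rho_c = {fit.rho_c:6.1f}  C = {fit.C:5.2f}")
print(f"truth    : Tc = {truth['Tc']:7.2f} K  B = {truth['B']:6.1f}  "
      f"rho_c = {truth['rho_c']:6.1f}  C = {truth['C']:5.2f}")

# The noiseless fit inverts the generating law to machine precision; with
# 2% multiplicative noise Tc typically lands within ~1 K of the truth.
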