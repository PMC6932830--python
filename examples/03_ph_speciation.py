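"""Charge-balance pH: pure water, a strong acid, and an ammonium buffer.

The proton concentration solves
[H+] + sum m [S m+] = [OH-] + sum n [S n-]
with every dissociation form a closed-form function of [H+]
(Newton-Raphson with a bracketed bisection fallback).
"""

import numpy as np

from biofilmsim.chemistry import (AcidBase, AcidBaseSystem, StrongIon,
                                  solve_ph, speciation_totals)

h, _ = solve_ph({}, AcidBaseSystem())
print(f"pure water:        pH = {-np.log10(h):.3f}")

system = AcidBaseSystem(species={"cl": StrongIon("cl", charge=-1)})
h, _ = solve_ph({"cl": 1e-3}, system)
print(f"1 mM strong acid:  pH = {-np.log10(h):.3f} "
      "(quadratic closed form gives 3.000)")

system = AcidBaseSystem(species={
    "nh4": AcidBase("nh4", ka=(5.6e-10,), charge0=+1),  # NH4+ <-> NH3
    "cl": StrongIon("cl", charge=-1)})
totals = {"nh4": 2e-3, "cl": 1e-3}
h, spec = solve_ph(totals, system)
nh4, nh3 = spec["nh4"]
print(f"half-titrated NH4+: pH = {-np.log10(h):.3f} "
      f"(pKa = {-np.log10(5.6e-10):.3f}); "
      f"NH4+ = {nh4:.2e} M, NH3 = {nh3:.2e} M")
back = speciation_totals(spec)
print(f"speciation mass balance recovers totals: {back['nh4']:.6e} M")
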