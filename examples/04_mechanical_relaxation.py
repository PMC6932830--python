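"""DEM relaxation: two overlapping cells push apart until the virial
pressure stabilises.

Soft-sphere Hookean contact F = K_n delta n - m_ij gamma_n v_ij resolves
the overlap; the loop stops when the average pressure
P = (sum m v.v + sum r_ij . F_ij) / 3V stops changing.
"""

import numpy as np

from biofilmsim.fixtures import make_scenario
from biofilmsim.mechanics import ForceParams, relax

cfg, pop = make_scenario("two_particle_overlap")
d0 = np.linalg.norm(pop.position[1] - pop.position[0])
rsum = float(pop.radius.sum())
print(f"initial centre distance {d0 * 1e6:.3f} um vs radius sum {rsum * 1e6:.3f} um "
      f"(overlap {100 * (rsum - d0) / pop.radius[0]:.0f}% of a radius)")

params = ForceParams(kn=1e-4, gamma_n=1e6)
steps, P = relax(pop, cfg.domain, params, dt=1e-7, max_steps=20_000, window=100)
d1 = np.linalg.norm(pop.position[1] - pop.position[0])
print(f"relaxed in {steps} Verlet steps; final distance {d1 * 1e6:.3f} um "
      f"(>= radius sum: {d1 >= rsum * (1 - 1e-3)}); exit pressure {P:.3e} Pa")
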