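"""Morphology statistics: height map, roughness, area density, floc shape.

Statistics are computed from particle positions and outer radii alone, so
they apply to any snapshot, including restart files.
"""

import numpy as np

from biofilmsim.driver import Simulation
from biofilmsim.fixtures import make_scenario
from biofilmsim.observables import (area_density, average_height, floc_stats,
                                    height_map, roughness)

cfg, pop = make_scenario("mushroom_colony", seed=3)
lx, ly, _ = cfg.domain.lengths

hm = height_map(pop, lx, ly, bin_size=1e-5)
print(f"hemispherical colony of {len(pop)} cells:")
print(f"  average height  {average_height(hm) * 1e6:7.3f} um")
print(f"  roughness       {roughness(hm) * 1e6:7.3f} um "
      "(nonzero: the colony is a bump on a bare substratum)")
print(f"  area density    {area_density(pop, lx, ly):.3e} kg/m^2")

d_eq, fd = floc_stats(pop, n_scales=4)
print(f"  equivalent diameter {d_eq * 1e6:.2f} um (sphere of equal biovolume)")
print(f"  box-counting dimension {fd:.2f} "
      "(~3 for a compact ball, lower for ramified flocs)")

flat_cfg, flat_pop = make_scenario("flat_film", seed=1)
hm_flat = height_map(flat_pop, lx, ly, bin_size=1e-5)
print(f"flat lattice film: roughness {roughness(hm_flat) * 1e6:.3f} um (by construction)")
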