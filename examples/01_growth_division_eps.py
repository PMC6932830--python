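"""Grow a single heterotroph to division and through EPS excretion.

Builds one 1.0 um cell, integrates dm/dt = mu m with forward Euler at a
fixed specific growth rate until it reaches the 1.3 um division threshold,
divides it, and keeps growing until the EPS shell triggers excretion.
"""

import numpy as np

from biofilmsim import FunctionalGroup, Pathway
from biofilmsim.agents import (Population, divide, eps_excrete,
                               integrate_growth, mass_from_diameter)

het = FunctionalGroup(
    name="HET", density=150.0, division_diameter=1.3e-6, death_diameter=6.5e-7,
    mu_max=6.94e-5, yield_=0.61, eps_yield=0.18, eps_density=30.0,
    shell_ratio_threshold=1.25,
    pathways=[Pathway(name="aerobic", monod={"substrate": 4e-3})])
eps = FunctionalGroup(name="EPS", density=30.0, biotic=False)

rng = np.random.default_rng(1)
pop = Population([het, eps])
pop.add("HET", (5e-5, 5e-5, 5e-7), mass_from_diameter(1.0e-6, het.density))

mu, dt = 5e-5, 900.0  # 0.18 h^-1 at 15-minute biological steps
steps_to_division = 0
while pop.diameter[0] < het.division_diameter:
    integrate_growth(pop, dt, mu=np.full(len(pop), mu))
    steps_to_division += 1
print(f"division threshold reached after {steps_to_division} steps "
      f"({steps_to_division * dt / 3600:.1f} h)")

m_before = pop.mass[0] + pop.outer_mass[0]
j = divide(pop, 0, rng)
print(f"daughter masses: {pop.mass[0]:.3e} and {pop.mass[j]:.3e} kg "
      f"(fraction {pop.mass[0] / (pop.mass[0] + pop.mass[j]):.3f}, "
      "drawn from Uniform(0.4, 0.6))")

while eps_excrete(pop, 0, rng) is None:
    integrate_growth(pop, dt, mu=np.full(len(pop), mu))
print(f"EPS excreted once outer/core diameter exceeded {het.shell_ratio_threshold}; "
      f"population is now {len(pop)} particles "
      f"({[pop.groups[g].name for g in pop.group]})")
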