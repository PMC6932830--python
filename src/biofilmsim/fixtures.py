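"""Seeded generators for initial states and ready-to-run test scenarios.

Everything the simulator consumes can be generated here from a seed: no
external data files are needed.  :func:`inoculate` places an initial
community (random on the substratum, on a lattice, or random in the box)
with overlap-free rejection sampling; :func:`make_scenario` returns small,
fully configured systems used throughout the test-suite and the examples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .agents import FunctionalGroup, Population, mass_from_diameter
from .config import SimConfig, parse_config
from .domain import Domain

__all__ = ["InoculumSpec", "PackingError", "inoculate", "make_scenario",
           "SCENARIOS", "nitrifying_config_yaml"]


class PackingError(RuntimeError):
    """Rejection sampling could not place the requested particles."""


@dataclass
class InoculumSpec:
    """What to inoculate: per-group counts, placement mode, size distribution."""

    counts: dict  # group name -> particle count
    mode: str = "random_substratum"  # | lattice | random_box
    diameter: float | tuple = 1e-6  # fixed, or (lo, hi) uniform range
    seed: int = 0

    def __post_init__(self):
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("inoculum counts must be >= 0")
        if self.mode not in ("random_substratum", "lattice", "random_box"):
            raise ValueError(f"unknown placement mode {self.mode!r}")


def _draw_diameter(spec: InoculumSpec, rng) -> float:
    if np.isscalar(spec.diameter):
        return float(spec.diameter)
    lo, hi = spec.diameter
    return float(rng.uniform(lo, hi))


def inoculate(spec: InoculumSpec, domain: Domain, groups: list[FunctionalGroup],
              rng: np.random.Generator | None = None) -> Population:
    """Place the inoculum; overlap-free, deterministic for a fixed seed.

    Substratum modes rest every particle on the floor (z = radius).
    Raises :class:`PackingError` after 10^4 consecutive rejections.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    pop = Population(groups)
    Lx, Ly, Lz = domain.lengths

    total = sum(spec.counts.values())
    if spec.mode == "lattice" and total:
        # square lattice on the substratum, row-major fill
        n_side = int(np.ceil(np.sqrt(total)))
        xs = (np.arange(n_side) + 0.5) * (Lx / n_side)
        ys = (np.arange(n_side) + 0.5) * (Ly / n_side)
        sites = [(x, y) for y in ys for x in xs]
    placed = 0

    # rough feasibility check for substratum modes
    if spec.mode != "random_box":
        d_max = spec.diameter if np.isscalar(spec.diameter) else spec.diameter[1]
        if total * d_max**2 > Lx * Ly:
            raise PackingError("requested inoculum footprint exceeds the substratum")

    for gname, count in spec.counts.items():
        for _ in range(count):
            d = _draw_diameter(spec, rng)
            r = 0.5 * d
            g = next(gr for gr in groups if gr.name == gname)
            mass = mass_from_diameter(d, g.density)
            rejections = 0
            while True:
                if spec.mode == "lattice":
                    x, y = sites[placed]
                    pos = np.array([x, y, r])
                elif spec.mode == "random_substratum":
                    pos = np.array([rng.uniform(0, Lx), rng.uniform(0, Ly), r])
                else:
                    pos = np.array([rng.uniform(0, Lx), rng.uniform(0, Ly),
                                    rng.uniform(r, Lz - r)])
                if len(pop) == 0:
                    break
                dx = domain.min_image(pop.position - pos)
                dist2 = np.einsum("ij,ij->i", dx, dx)
                if np.all(dist2 >= (pop.radius + r) ** 2):
                    break
                rejections += 1
                if spec.mode == "lattice" or rejections >= 10_000:
                    raise PackingError(
                        f"could not place particle {placed + 1}/{total} "
                        f"after {rejections} rejections")
            pop.add(gname, pos, mass)
            placed += 1
    return pop


# -- scenarios ---------------------------------------------------------------


def nitrifying_config_yaml(t_end: float = 0.0, seed: int = 1) -> str:
    """Config for a miniature HET/AOB/NOB nitrifying biofilm.

    A desk-scale analogue of a multi-group nitrifying reactor biofilm:
    100x100x100 um domain, ample aerated oxygen and ammonium in the
    influent, no nitrite/nitrate inflow, and a chemostat bulk sized so
    heterotroph growth turns organic-substrate-limited as the film matures.
    Kinetic and stoichiometric constants are standard activated-sludge
    style values.
    """
    return f"""
domain:
  lengths: [1.0e-4, 1.0e-4, 1.0e-4]
  periodic: [true, true, false]
  voxel_size: 1.0e-5
  boundary_layer_height: 2.0e-5

solutes:
  substrate: {{diffusivity: 1.6e-9, s_bulk: 4.0e-3, s_in: 1.5e-3}}
  o2:        {{diffusivity: 2.3e-9, s_bulk: 0.01, s_in: 0.01, fixed_bulk: true}}
  nh4:       {{diffusivity: 1.9e-9, s_bulk: 0.1, s_in: 0.1}}
  no2:       {{diffusivity: 1.9e-9, s_bulk: 0.0, s_in: 0.0}}
  no3:       {{diffusivity: 1.9e-9, s_bulk: 0.0, s_in: 0.0}}

groups:
  HET:
    density: 150.0
    division_diameter: 1.3e-6
    death_diameter: 6.5e-7
    mu_max: 6.94e-5      # ~6 d^-1
    decay_rate: 2.3e-6   # ~0.2 d^-1
    yield: 0.61
    eps_yield: 0.18
    eps_density: 30.0
    shell_ratio_threshold: 1.25
    adhesive: true
    pathways:
      aerobic:
        monod: {{substrate: 4.0e-3, o2: 2.0e-4}}
        stoich: {{substrate: -1.6393, o2: -0.6393}}
      anoxic_no3:
        eta: 0.6
        monod: {{substrate: 4.0e-3, no3: 5.0e-4}}
        inhibition: {{o2: 2.0e-4}}
        stoich: {{substrate: -1.6393, no3: -0.2236}}
      anoxic_no2:
        eta: 0.6
        monod: {{substrate: 4.0e-3, no2: 5.0e-4}}
        inhibition: {{o2: 2.0e-4}}
        stoich: {{substrate: -1.6393, no2: -0.3739}}
  AOB:
    density: 150.0
    division_diameter: 1.3e-6
    death_diameter: 6.5e-7
    mu_max: 1.4e-5       # ~1.2 d^-1
    decay_rate: 1.3e-6
    yield: 0.33
    pathways:
      aerobic:
        monod: {{nh4: 1.0e-3, o2: 5.4e-4}}
        stoich: {{nh4: -3.0303, o2: -9.3939, no2: 3.0303}}
  NOB:
    density: 150.0
    division_diameter: 1.3e-6
    death_diameter: 6.5e-7
    mu_max: 1.0e-5       # ~0.86 d^-1
    decay_rate: 1.3e-6
    yield: 0.083
    pathways:
      aerobic:
        monod: {{no2: 1.3e-3, o2: 6.8e-4}}
        stoich: {{no2: -12.048, o2: -12.735, no3: 12.048}}
  EPS:
    density: 30.0
    adhesive: true
    biotic: false
  DEAD:
    density: 150.0
    biotic: false
    decay_rate: 2.0e-6
    decay_stoich: {{substrate: 1.0}}

bulk:
  flow_rate: 2.0e-16     # m^3 s^-1
  volume: 2.0e-12        # m^3; micro-reactor the domain is a replicate of
  biofilm_area: 1.0e-8   # m^2, equal to the substratum

mechanics:
  kn: 1.0e-4
  gamma_n: 1.0e5
  hamaker: 1.0e-22   # weak EPS cohesion: equilibrium overlap ~2% of a radius
  relax_max_steps: 800
  window: 50

timesteps: {{bio: 900.0, mech: 5.0e-8}}
diffusion: {{tol: 1.0e-6, max_iters: 200000}}

run: {{t_end: {t_end}, seed: {seed}}}
"""


SCENARIOS = ("flat_film", "two_particle_overlap", "mushroom_colony",
             "nitrifying_community", "decay_only")


def make_scenario(name: str, seed: int = 1):
    """Return ``(SimConfig, Population)`` for a registered small scenario."""
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; known: {', '.join(SCENARIOS)}")
    rng = np.random.default_rng(seed)

    if name == "nitrifying_community":
        cfg = parse_config(nitrifying_config_yaml(t_end=20 * 900.0, seed=seed))
        spec = InoculumSpec(counts={"HET": 16, "AOB": 12, "NOB": 12},
                            diameter=1.0e-6, seed=seed)
        pop = inoculate(spec, cfg.domain, cfg.groups, rng)
        return cfg, pop

    if name == "decay_only":
        cfg = parse_config(nitrifying_config_yaml(t_end=20 * 900.0, seed=seed))
        # starve the film: no nutrients anywhere
        for s in cfg.solutes.values():
            s.s_bulk = 0.0
            s.s_in = 0.0
        cfg.bulk.s_bulk = {n: 0.0 for n in cfg.solutes}
        spec = InoculumSpec(counts={"HET": 20}, diameter=1.0e-6, seed=seed)
        pop = inoculate(spec, cfg.domain, cfg.groups, rng)
        return cfg, pop

    if name == "flat_film":
        cfg = parse_config(nitrifying_config_yaml(t_end=10 * 900.0, seed=seed))
        spec = InoculumSpec(counts={"HET": 100}, mode="lattice",
                            diameter=1.0e-6, seed=seed)
        pop = inoculate(spec, cfg.domain, cfg.groups, rng)
        return cfg, pop

    if name == "mushroom_colony":
        # a hemispherical cap of HET on the substratum centre
        cfg = parse_config(nitrifying_config_yaml(t_end=10 * 900.0, seed=seed))
        pop = Population(cfg.groups)
        g = cfg.group("HET")
        d = 1.0e-6
        centre = np.array([5.0e-5, 5.0e-5, 0.0])
        cap_radius = 8.0e-6
        n_target = 60
        placed = 0
        while placed < n_target:
            u = rng.normal(size=3)
            u[2] = abs(u[2])
            u /= np.linalg.norm(u)
            rad = cap_radius * rng.uniform() ** (1 / 3)
            pos = centre + rad * u
            pos[2] = max(pos[2], d / 2)
            cand = np.asarray(pos)
            if len(pop):
                dx = cfg.domain.min_image(pop.position - cand)
                if np.any(np.einsum("ij,ij->i", dx, dx) < (0.9 * d) ** 2):
                    continue
            pop.add("HET", cand, mass_from_diameter(d, g.density))
            placed += 1
        return cfg, pop

    # two_particle_overlap: exactly two spheres overlapping by 10% of a radius
    cfg = parse_config(nitrifying_config_yaml(t_end=0.0, seed=seed))
    pop = Population(cfg.groups)
    g = cfg.group("HET")
    d = 1.0e-6
    r = d / 2
    m = mass_from_diameter(d, g.density)
    z = 5.0e-5
    pop.add("HET", [4.0e-5, 5.0e-5, z], m)
    pop.add("HET", [4.0e-5 + 1.9 * r, 5.0e-5, z], m)  # overlap = 0.1 r
    return cfg, pop
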