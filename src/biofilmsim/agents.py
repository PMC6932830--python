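"""Microbial agents: state arrays, functional groups, and biological events.

Each agent is a soft sphere with position, velocity, force, mass, density,
diameter and an optional EPS shell described by an outer mass and outer
diameter.  Agents belong to a functional group (HET, AOB, NOB, EPS, DEAD or
user-defined) that carries the shared parameters: kinetics, yields, density,
division and death thresholds and EPS-shell settings.

Agent state is stored as a struct-of-arrays :class:`Population` so that the
per-step updates vectorise; the event operations (:func:`divide`,
:func:`check_death`, :func:`eps_excrete`, ...) act on single agents by index
and honour the per-agent contracts:

* growth integrates ``dm/dt = mu * m`` with forward Euler over one
  biological step,
* division splits the parent mass with a Uniform(0.4, 0.6) fraction and is
  exactly mass-conserving,
* agents shrinking below the death diameter become DEAD; below a tenth of
  it they are removed,
* HET agents whose EPS shell grows beyond a relative-thickness threshold
  excrete a Uniform(0.4, 0.6) fraction of the shell as a free EPS particle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ALIVE",
    "DEAD",
    "REMOVE",
    "Pathway",
    "FunctionalGroup",
    "Population",
    "integrate_growth",
    "divide",
    "check_death",
    "death_status",
    "dead_cell_lysis_rate",
    "lysis_step",
    "eps_excrete",
    "random_unit_vector",
    "load_particles",
    "save_particles",
]

ALIVE = 0
DEAD = 1
REMOVE = 2


def mass_from_diameter(d, density):
    return np.pi / 6.0 * density * np.asarray(d) ** 3


def diameter_from_mass(m, density):
    return (6.0 * np.asarray(m) / (np.pi * density)) ** (1.0 / 3.0)


def random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    """Uniform direction on the unit sphere (normalised Gaussian triple)."""
    while True:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
        if n > 1e-12:
            return v / n


@dataclass
class Pathway:
    """One metabolic pathway: Monod terms, anoxic factor, and stoichiometry.

    ``monod`` maps solute name -> half-saturation constant K (kg m^-3);
    ``stoich`` maps solute name -> yield-normalised coefficient
    (kg solute per kg new biomass; consumption negative).
    ``eta`` is the reduction factor (1 aerobic, etaHET anoxic).
    """

    name: str
    eta: float = 1.0
    monod: dict = field(default_factory=dict)
    stoich: dict = field(default_factory=dict)
    inhibition: dict = field(default_factory=dict)  # solute -> K_I (term K/(K+S))


@dataclass
class FunctionalGroup:
    """Shared parameters of one microbial type."""

    name: str
    density: float  # kg m^-3
    division_diameter: float = 0.0  # m; 0 disables division
    death_diameter: float = 0.0  # m; 0 disables death
    mu_max: float = 0.0  # s^-1
    decay_rate: float = 0.0  # s^-1, first-order
    yield_: float = 1.0  # biomass yield on substrate, (0, 1]
    pathways: list = field(default_factory=list)
    # decay stoichiometry (e.g. oxygen demand of endogenous respiration)
    decay_stoich: dict = field(default_factory=dict)
    # EPS shell parameters (HET only)
    eps_yield: float = 0.0
    eps_density: float = 0.0
    shell_ratio_threshold: float = 0.0  # outer-diameter / diameter trigger
    biotic: bool = True  # False for EPS and DEAD groups
    adhesive: bool = False  # feels EPS adhesion (HET shells, free EPS)

    def __post_init__(self):
        if self.division_diameter and self.death_diameter:
            if not self.division_diameter > self.death_diameter > 0:
                raise ValueError(
                    f"group {self.name}: need division diameter > death diameter > 0"
                )
        if not 0 < self.yield_ <= 1:
            raise ValueError(f"group {self.name}: yield must be in (0, 1]")
        for r in (self.mu_max, self.decay_rate, self.eps_yield):
            if r < 0:
                raise ValueError(f"group {self.name}: rates must be >= 0")


class Population:
    """Struct-of-arrays container for all agents in a simulation."""

    _FIELDS = ("id", "group", "position", "velocity", "force", "mass",
               "density", "outer_mass", "growth_rate")

    def __init__(self, groups: list[FunctionalGroup]):
        self.groups = list(groups)
        self._by_name = {g.name: i for i, g in enumerate(self.groups)}
        self.id = np.empty(0, dtype=np.int64)
        self.group = np.empty(0, dtype=np.int32)
        self.position = np.empty((0, 3))
        self.velocity = np.empty((0, 3))
        self.force = np.empty((0, 3))
        self.mass = np.empty(0)
        self.density = np.empty(0)
        self.outer_mass = np.empty(0)
        self.growth_rate = np.empty(0)
        self._next_id = 0

    def __len__(self):
        return self.id.size

    def group_index(self, name: str) -> int:
        return self._by_name[name]

    def group_of(self, i: int) -> FunctionalGroup:
        return self.groups[self.group[i]]

    # -- derived geometry ---------------------------------------------------

    @property
    def diameter(self) -> np.ndarray:
        return diameter_from_mass(self.mass, self.density)

    @property
    def radius(self) -> np.ndarray:
        return 0.5 * self.diameter

    @property
    def outer_diameter(self) -> np.ndarray:
        """Core + EPS-shell diameter; equals the core diameter for shell-free groups."""
        core_vol = self.mass / self.density
        shell_vol = np.zeros_like(core_vol)
        for gi, g in enumerate(self.groups):
            if g.eps_density > 0:
                sel = self.group == gi
                shell_vol[sel] = self.outer_mass[sel] / g.eps_density
        return (6.0 / np.pi * (core_vol + shell_vol)) ** (1.0 / 3.0)

    @property
    def outer_radius(self) -> np.ndarray:
        return 0.5 * self.outer_diameter

    @property
    def total_biomass(self) -> float:
        return float(self.mass.sum() + self.outer_mass.sum())

    def biomass_by_group(self) -> dict:
        out = {}
        for gi, g in enumerate(self.groups):
            sel = self.group == gi
            out[g.name] = float(self.mass[sel].sum() + self.outer_mass[sel].sum())
        return out

    # -- mutation -----------------------------------------------------------

    def add(self, group, position, mass, *, velocity=None, outer_mass=0.0,
            density=None) -> int:
        """Append one agent; returns its index.  Ids are never reused."""
        gi = self.group_index(group) if isinstance(group, str) else int(group)
        g = self.groups[gi]
        self.id = np.append(self.id, self._next_id)
        self._next_id += 1
        self.group = np.append(self.group, np.int32(gi))
        self.position = np.vstack([self.position, np.asarray(position, dtype=float)])
        vel = np.zeros(3) if velocity is None else np.asarray(velocity, dtype=float)
        self.velocity = np.vstack([self.velocity, vel])
        self.force = np.vstack([self.force, np.zeros(3)])
        self.mass = np.append(self.mass, float(mass))
        self.density = np.append(self.density, g.density if density is None else float(density))
        self.outer_mass = np.append(self.outer_mass, float(outer_mass))
        self.growth_rate = np.append(self.growth_rate, 0.0)
        return len(self) - 1

    def remove(self, indices):
        keep = np.ones(len(self), dtype=bool)
        keep[np.asarray(indices, dtype=int)] = False
        for name in self._FIELDS:
            setattr(self, name, getattr(self, name)[keep])

    def copy(self) -> "Population":
        new = Population(self.groups)
        for name in self._FIELDS:
            setattr(new, name, getattr(self, name).copy())
        new._next_id = self._next_id
        return new


# -- biological operations ---------------------------------------------------


def integrate_growth(pop: Population, dt_bio: float, mu=None) -> np.ndarray:
    """Forward-Euler growth over one biological step: ``m <- m (1 + mu dt)``.

    *mu* defaults to the stored per-agent growth rates.  HET-like groups
    (``eps_yield > 0``) accumulate shell mass at the configured EPS share of
    (positive) growth, ``Y_EPS / Y`` per unit of new core biomass.  A decay
    step that would drive the mass non-positive is floored at half the
    removal-threshold mass and left to death processing.  Returns the
    indices of floored agents.
    """
    if dt_bio <= 0:
        raise ValueError("dt_bio must be positive")
    if mu is None:
        mu = pop.growth_rate
    mu = np.asarray(mu, dtype=float)
    m_old = pop.mass.copy()
    new_mass = m_old * (1.0 + mu * dt_bio)

    floored = np.array([], dtype=int)
    bad = new_mass <= 0
    if np.any(bad):
        floor = np.empty(len(pop))
        for gi, g in enumerate(pop.groups):
            d_rm = (g.death_diameter / 10.0) if g.death_diameter else 0.0
            floor[pop.group == gi] = 0.5 * mass_from_diameter(d_rm, g.density)
        new_mass[bad] = np.maximum(floor[bad], 1e-300)
        floored = np.flatnonzero(bad)
    pop.mass = new_mass

    for gi, g in enumerate(pop.groups):
        if g.eps_yield > 0:
            sel = pop.group == gi
            growth = np.maximum(mu[sel], 0.0) * m_old[sel] * dt_bio
            pop.outer_mass[sel] += (g.eps_yield / g.yield_) * growth
    return floored


def divide(pop: Population, i: int, rng: np.random.Generator,
           distance_mode: str = "radius_sum") -> int:
    """Split agent *i* into two daughters; returns the new daughter's index.

    The first daughter keeps the parent's slot, id and position and receives
    a Uniform(0.4, 0.6) fraction of the parent mass; the second is placed at
    a uniformly random direction at centre distance r1 + r2 (or d1 + d2 with
    ``distance_mode='diameter_sum'``).  The EPS shell splits with the same
    fraction.  Total mass is conserved exactly.  A placement that would sink
    the daughter below the substratum is reflected to z >= radius.
    """
    g = pop.group_of(i)
    if g.division_diameter <= 0 or pop.diameter[i] < g.division_diameter:
        raise ValueError(
            f"divide called below the division threshold "
            f"(d={pop.diameter[i]:.3e} < {g.division_diameter:.3e})"
        )
    f = rng.uniform(0.4, 0.6)
    m_parent = pop.mass[i]
    om_parent = pop.outer_mass[i]
    m1 = f * m_parent
    m2 = m_parent - m1
    pop.mass[i] = m1
    pop.outer_mass[i] = f * om_parent

    r1 = 0.5 * diameter_from_mass(m1, g.density)
    r2 = 0.5 * diameter_from_mass(m2, g.density)
    if distance_mode == "radius_sum":
        d = r1 + r2
    elif distance_mode == "diameter_sum":
        d = 2.0 * (r1 + r2)
    else:
        raise ValueError(f"unknown division distance mode {distance_mode!r}")
    direction = random_unit_vector(rng)
    pos2 = pop.position[i] + d * direction
    if pos2[2] < r2:  # reflect about z = r2 instead of resampling: draw count stays fixed
        pos2[2] = 2.0 * r2 - pos2[2]
    j = pop.add(int(pop.group[i]), pos2, m2, velocity=pop.velocity[i],
                outer_mass=om_parent - pop.outer_mass[i])
    return j


def death_status(pop: Population) -> np.ndarray:
    """Vectorised death rule: ALIVE / DEAD / REMOVE per agent.

    DEAD strictly below the death diameter (an agent exactly at the
    threshold stays alive); REMOVE strictly below a tenth of it.  Groups
    with no death threshold (EPS, DEAD, ...) use their own threshold of 0,
    except that DEAD-group agents keep shrinking and are removed below the
    configured removal size.
    """
    status = np.full(len(pop), ALIVE, dtype=np.int8)
    d = pop.diameter
    for gi, g in enumerate(pop.groups):
        if g.death_diameter <= 0:
            continue
        sel = pop.group == gi
        status[sel & (d < g.death_diameter)] = DEAD
        status[sel & (d < g.death_diameter / 10.0)] = REMOVE
    return status


def check_death(pop: Population, i: int) -> int:
    """Death rule for a single agent (see :func:`death_status`)."""
    return int(death_status(pop)[i])


def dead_cell_lysis_rate(pop: Population, i: int, lysis_rate: float) -> float:
    """First-order substrate release rate (kg s^-1) of a DEAD agent."""
    if lysis_rate < 0:
        raise ValueError("lysis rate must be >= 0")
    if pop.group_of(i).biotic:
        raise ValueError("lysis applies to DEAD-type agents only")
    return float(lysis_rate * pop.mass[i])


def lysis_step(pop: Population, mask: np.ndarray, lysis_rate: float,
               dt: float) -> float:
    """Decrement DEAD biomass by first-order lysis; returns released mass (kg)."""
    if lysis_rate < 0:
        raise ValueError("lysis rate must be >= 0")
    dm = np.minimum(pop.mass[mask] * lysis_rate * dt, pop.mass[mask])
    pop.mass[mask] -= dm
    return float(dm.sum())


def eps_excrete(pop: Population, i: int, rng: np.random.Generator,
                eps_group: int | str = "EPS"):
    """Excrete part of agent *i*'s EPS shell as a free EPS particle.

    No-op (returns None) unless the relative shell thickness
    outer-diameter / diameter exceeds the group threshold.  A
    Uniform(0.4, 0.6) fraction of the shell mass becomes a new EPS particle
    placed in contact with the agent at a uniformly random direction
    (reflected above the substratum); shell mass is conserved exactly.
    """
    g = pop.group_of(i)
    if g.shell_ratio_threshold <= 0 or g.eps_density <= 0:
        return None
    if pop.outer_diameter[i] / pop.diameter[i] <= g.shell_ratio_threshold:
        return None
    frac = rng.uniform(0.4, 0.6)
    m_eps = frac * pop.outer_mass[i]
    pop.outer_mass[i] -= m_eps

    gi_eps = pop.group_index(eps_group) if isinstance(eps_group, str) else int(eps_group)
    rho_eps = pop.groups[gi_eps].density
    r_eps = 0.5 * diameter_from_mass(m_eps, rho_eps)
    d = pop.outer_radius[i] + r_eps
    direction = random_unit_vector(rng)
    pos = pop.position[i] + d * direction
    if pos[2] < r_eps:
        pos[2] = max(2.0 * r_eps - pos[2], r_eps)
    return pop.add(gi_eps, pos, m_eps, velocity=pop.velocity[i])


# -- particle text format ----------------------------------------------------
# one record per line: id  group  diameter  density  x  y  z  outer_diameter


def save_particles(pop: Population, path) -> None:
    d = pop.diameter
    od = pop.outer_diameter
    with open(path, "w") as fh:
        fh.write("# id group diameter density x y z outer_diameter\n")
        for i in range(len(pop)):
            g = pop.groups[pop.group[i]].name
            x, y, z = pop.position[i]
            fh.write(f"{pop.id[i]} {g} {d[i]:.12e} {pop.density[i]:.12e} "
                     f"{x:.12e} {y:.12e} {z:.12e} {od[i]:.12e}\n")


def load_particles(path, groups: list[FunctionalGroup]) -> Population:
    pop = Population(groups)
    max_id = -1
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split()
            pid, gname = int(tok[0]), tok[1]
            dia, rho = float(tok[2]), float(tok[3])
            pos = [float(tok[4]), float(tok[5]), float(tok[6])]
            od = float(tok[7])
            gi = pop.group_index(gname)
            g = groups[gi]
            mass = mass_from_diameter(dia, rho)
            outer_mass = 0.0
            if g.eps_density > 0 and od > dia:
                shell_vol = np.pi / 6.0 * (od**3 - dia**3)
                outer_mass = shell_vol * g.eps_density
            i = pop.add(gi, pos, mass, outer_mass=outer_mass, density=rho)
            pop.id[i] = pid
            max_id = max(max_id, pid)
    pop._next_id = max_id + 1
    return pop
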