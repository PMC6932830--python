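"""Soft-sphere DEM mechanics: neighbour lists, pair forces, Verlet
integration, virial pressure, and relaxation to mechanical equilibrium.

Forces
------
* Hookean contact with viscoelastic damping on overlapping cores:
  ``F_i = K_n delta n_ij - m_ij gamma_n v_ij`` with overlap
  ``delta = r_i + r_j - |x_j - x_i|``, effective mass
  ``m_ij = m_i m_j / (m_i + m_j)`` and ``n_ij`` the unit vector from j to i.
* EPS adhesion as a van der Waals attraction between shell-bearing agents:
  ``F = H_a r_ij / (12 h_min^2)`` directed from i toward j, with effective
  outer radius ``r_ij = R_i R_j/(R_i + R_j)`` and the separation floored at
  ``h_floor`` to regularise the 1/h^2 singularity.
* Drag against a prescribed fluid velocity field:
  ``F_d = -(V_p / eps_f) eps_s beta (u_p - U_f)`` with the Stokes-form
  correction ``beta = 18 mu_f eps_f / d_p^2`` by default.

Mechanical equilibrium is declared when the community's average (virial)
pressure ``P = (sum m v.v + sum_{i<j} r_ij . F_ij) / (3 V)`` stops changing
over a sliding window.  Rotational motion is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .agents import Population
from .domain import Domain, Grid, locate_voxel

__all__ = [
    "ForceParams",
    "NeighborList",
    "build_neighbor_list",
    "pair_forces",
    "contact_force",
    "eps_adhesion_force",
    "drag_force",
    "compute_forces",
    "verlet_step",
    "average_pressure",
    "relax",
]


@dataclass
class ForceParams:
    """Mechanical interaction parameters (SI units)."""

    kn: float = 1e-4  # normal elastic constant, N m^-1
    gamma_n: float = 1e5  # viscoelastic damping constant, s^-1 scale
    hamaker: float = 0.0  # Hamaker coefficient, J (0 disables adhesion)
    h_floor: float = 1e-9  # minimum-separation floor, m
    adhesion_cutoff: float = 1.5  # x (R_i + R_j)
    fluid_viscosity: float = 1e-3  # Pa s, for the Stokes beta
    fluid_density: float = 1000.0  # kg m^-3
    boundary: tuple = ("wrap", "wrap", "reflect")  # per-axis fixed-face behaviour

    def __post_init__(self):
        for v, n in ((self.kn, "K_n"), (self.gamma_n, "gamma_n"),
                     (self.hamaker, "H_a"), (self.h_floor, "h_floor")):
            if v < 0:
                raise ValueError(f"{n} must be >= 0")


@dataclass
class NeighborList:
    """Symmetric pair list within cutoff + skin (minimum image on periodic axes)."""

    pairs: np.ndarray  # (M, 2) int array, i < j
    cutoff: float
    skin: float
    ref_positions: np.ndarray = field(repr=False)

    def needs_rebuild(self, positions: np.ndarray, domain: Domain) -> bool:
        """True once any particle moved more than skin/2 since the build."""
        if positions.shape != self.ref_positions.shape:
            return True
        d = domain.min_image(positions - self.ref_positions)
        return bool(np.any(np.einsum("ij,ij->i", d, d) > (0.5 * self.skin) ** 2))


def _tree(positions: np.ndarray, domain: Domain) -> cKDTree:
    # Mixed periodicity: pad non-periodic axes so the periodic image across
    # them is always farther than any physical cutoff.
    box = [2.0 * L if not per else L
           for L, per in zip(domain.lengths, domain.periodic)]
    wrapped = domain.wrap(positions)
    return cKDTree(wrapped, boxsize=box)


def build_neighbor_list(pop: Population, domain: Domain, cutoff: float,
                        skin: float = 0.0) -> NeighborList:
    """Cell-binned construction of all pairs with distance < cutoff + skin."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = len(pop)
    if n < 2:
        pairs = np.empty((0, 2), dtype=np.intp)
    else:
        tree = _tree(pop.position, domain)
        pairs = tree.query_pairs(cutoff + skin, output_type="ndarray")
        if pairs.size:
            pairs = np.sort(pairs, axis=1)
            pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
    return NeighborList(pairs=pairs, cutoff=cutoff, skin=skin,
                        ref_positions=pop.position.copy())


def contact_force(ri, rj, xi, xj, vi, vj, mi, mj, params: ForceParams,
                  domain: Domain | None = None):
    """Hookean contact force on particle i from particle j (zero if no overlap)."""
    dx = np.asarray(xi, dtype=float) - np.asarray(xj, dtype=float)
    if domain is not None:
        dx = domain.min_image(dx)
    dist = float(np.linalg.norm(dx))
    delta = ri + rj - dist
    if delta <= 0:
        return np.zeros(3)
    if dist < 1e-30:
        n_ij = np.array([0.0, 0.0, 1.0])  # deterministic fallback axis
    else:
        n_ij = dx / dist
    m_eff = mi * mj / (mi + mj)
    v_ij = np.asarray(vi, dtype=float) - np.asarray(vj, dtype=float)
    return params.kn * delta * n_ij - m_eff * params.gamma_n * v_ij


def eps_adhesion_force(Ri, Rj, xi, xj, params: ForceParams,
                       domain: Domain | None = None):
    """van der Waals adhesion on particle i (attractive, toward j)."""
    dx = np.asarray(xj, dtype=float) - np.asarray(xi, dtype=float)
    if domain is not None:
        dx = domain.min_image(dx)
    dist = float(np.linalg.norm(dx))
    if dist >= params.adhesion_cutoff * (Ri + Rj) or dist < 1e-30:
        return np.zeros(3)
    h = dist - (Ri + Rj)
    h_min = max(h, params.h_floor)
    r_eff = Ri * Rj / (Ri + Rj)
    return params.hamaker * r_eff / (12.0 * h_min**2) * (dx / dist)


def drag_force(pop: Population, grid: Grid, velocity_field: np.ndarray,
               params: ForceParams) -> np.ndarray:
    """Fluid drag on every particle from a prescribed voxel-centred field.

    The per-voxel solid fraction eps_s is the summed particle volume over
    the voxel volume; an over-packed voxel (eps_s >= 1) is an error.
    """
    n = len(pop)
    F = np.zeros((n, 3))
    if n == 0:
        return F
    idx = locate_voxel(grid, pop.position)
    vol = pop.mass / pop.density
    eps_s_grid = np.zeros(grid.shape)
    np.add.at(eps_s_grid, (idx[:, 0], idx[:, 1], idx[:, 2]), vol)
    eps_s_grid /= grid.voxel_volume
    eps_s = eps_s_grid[idx[:, 0], idx[:, 1], idx[:, 2]]
    if np.any(eps_s >= 1.0):
        raise ValueError("over-packed voxel: solid volume fraction >= 1")
    eps_f = 1.0 - eps_s
    u_f = velocity_field[idx[:, 0], idx[:, 1], idx[:, 2]]
    d_p = pop.diameter
    beta = 18.0 * params.fluid_viscosity * eps_f / d_p**2
    F = -(vol / eps_f * eps_s * beta)[:, None] * (pop.velocity - u_f)
    return F


def pair_forces(pop: Population, domain: Domain, params: ForceParams,
                nlist: NeighborList):
    """Pairwise contact + adhesion forces.

    Returns ``(F, virial)``: the per-particle force array and the summed
    pair virial ``sum_{i<j} r_ij . F_ij`` (r_ij from j to i, F_ij on i).
    """
    n = len(pop)
    F = np.zeros((n, 3))
    virial = 0.0
    if nlist.pairs.size == 0:
        return F, virial
    i, j = nlist.pairs[:, 0], nlist.pairs[:, 1]
    dx = domain.min_image(pop.position[i] - pop.position[j])  # j -> i
    dist = np.linalg.norm(dx, axis=1)
    coincident = dist < 1e-30
    if np.any(coincident):
        dx[coincident] = (0.0, 0.0, 1e-30)
        dist[coincident] = 1e-30
    n_ij = dx / dist[:, None]

    r = pop.radius
    delta = r[i] + r[j] - dist
    contact = delta > 0
    if np.any(contact):
        m_eff = pop.mass[i] * pop.mass[j] / (pop.mass[i] + pop.mass[j])
        v_ij = pop.velocity[i] - pop.velocity[j]
        Fc = np.zeros_like(dx)
        Fc[contact] = (params.kn * delta[contact, None] * n_ij[contact]
                       - (m_eff[contact] * params.gamma_n)[:, None] * v_ij[contact])
        np.add.at(F, i, Fc)
        np.add.at(F, j, -Fc)
        virial += float(np.einsum("ij,ij->", dx, Fc))

    if params.hamaker > 0:
        adhesive = np.array([g.adhesive for g in pop.groups], dtype=bool)
        both = adhesive[pop.group[i]] & adhesive[pop.group[j]]
        if np.any(both):
            R = pop.outer_radius
            within = both & (dist < params.adhesion_cutoff * (R[i] + R[j]))
            if np.any(within):
                h = dist - (R[i] + R[j])
                h_min = np.maximum(h, params.h_floor)
                r_eff = R[i] * R[j] / (R[i] + R[j])
                mag = params.hamaker * r_eff / (12.0 * h_min**2)
                Fa = np.zeros_like(dx)
                Fa[within] = -mag[within, None] * n_ij[within]  # toward j
                np.add.at(F, i, Fa)
                np.add.at(F, j, -Fa)
                virial += float(np.einsum("ij,ij->", dx, Fa))
    return F, virial


def compute_forces(pop: Population, domain: Domain, params: ForceParams,
                   nlist: NeighborList, grid: Grid | None = None,
                   velocity_field: np.ndarray | None = None):
    """Total force on every particle; returns ``(F, pair_virial)``."""
    F, virial = pair_forces(pop, domain, params, nlist)
    if velocity_field is not None and grid is not None:
        F = F + drag_force(pop, grid, velocity_field, params)
    return F, virial


def average_pressure(pop: Population, pair_virial: float) -> float:
    """Virial pressure over the summed particle volume (Pa)."""
    if len(pop) == 0:
        raise ValueError("average pressure of an empty system is undefined")
    V = float(np.sum(pop.mass / pop.density))
    kinetic = float(np.einsum("i,ij,ij->", pop.mass, pop.velocity, pop.velocity))
    return (kinetic + pair_virial) / (3.0 * V)


def _apply_boundaries(pop: Population, domain: Domain, params: ForceParams):
    """Wrap/reflect positions; returns indices to remove (remove-style faces)."""
    to_remove = []
    r = pop.radius
    for ax in range(3):
        L = domain.lengths[ax]
        x = pop.position[:, ax]
        if domain.periodic[ax]:
            pop.position[:, ax] = x % L
            continue
        mode = params.boundary[ax]
        lo_bound = r if ax == 2 else np.zeros_like(x)  # substratum: sphere rests on it
        below = x < lo_bound
        above = x > L
        if mode == "remove":
            to_remove.extend(np.flatnonzero(below | above).tolist())
        elif mode in ("reflect", "wrap"):
            if np.any(below):
                pop.position[below, ax] = 2 * lo_bound[below] - x[below] if ax == 2 else -x[below]
                pop.velocity[below, ax] *= -1
            if np.any(above):
                pop.position[above, ax] = 2 * L - x[above]
                pop.velocity[above, ax] *= -1
        else:
            raise ValueError(f"unknown boundary behaviour {mode!r}")
    # clamp pathological reflections back inside
    for ax in range(3):
        if not domain.periodic[ax]:
            pop.position[:, ax] = np.clip(pop.position[:, ax], 0.0, domain.lengths[ax])
    if pop.position.shape[0]:
        pop.position[:, 2] = np.maximum(pop.position[:, 2], 0.0)
    return sorted(set(to_remove))


def verlet_step(pop: Population, domain: Domain, params: ForceParams,
                nlist: NeighborList, dt: float, grid: Grid | None = None,
                velocity_field: np.ndarray | None = None,
                max_displacement: float = np.inf,
                limit: float | None = None):
    """One velocity-Verlet step (translation only).

    Uses the stored ``pop.force`` as the current forces, drifts, recomputes
    forces, and completes the velocity half-kick.  Returns the pair virial
    of the recomputed forces.  Raises if any displacement exceeds
    *max_displacement* (instability guard, typically the voxel size).

    *limit*, if set, caps the per-step displacement (and the velocity that
    produced it) at that length — quasi-static relaxation in the style of
    limited-distance NVE integration, which keeps deeply overlapping fresh
    daughters or EPS particles from being ejected ballistically.
    """
    m = pop.mass[:, None]
    pop.velocity += 0.5 * dt * pop.force / m
    if limit is not None and len(pop):
        speed = np.linalg.norm(pop.velocity, axis=1)
        over = speed * dt > limit
        if np.any(over):
            pop.velocity[over] *= (limit / dt / speed[over])[:, None]
    disp = dt * pop.velocity
    if np.any(np.abs(disp) > max_displacement):
        raise RuntimeError(
            f"unstable Verlet step: displacement exceeds {max_displacement:.3e} m; "
            "reduce dt_mech"
        )
    pop.position += disp
    removed = _apply_boundaries(pop, domain, params)
    if removed:
        pop.remove(removed)
        nlist.pairs = np.empty((0, 2), dtype=np.intp)  # force rebuild
        nlist.ref_positions = np.empty((0, 3))
    if nlist.needs_rebuild(pop.position, domain):
        new = build_neighbor_list(pop, domain, nlist.cutoff, nlist.skin)
        nlist.pairs, nlist.ref_positions = new.pairs, new.ref_positions
    F, virial = compute_forces(pop, domain, params, nlist, grid, velocity_field)
    pop.force = F
    pop.velocity += 0.5 * dt * F / pop.mass[:, None]
    return virial


def relax(pop: Population, domain: Domain, params: ForceParams, dt: float,
          pressure_tol: float = 1e-3, max_steps: int = 10_000,
          window: int = 100, pressure_floor: float = 1e-12,
          grid: Grid | None = None, velocity_field: np.ndarray | None = None,
          cutoff: float | None = None, skin: float | None = None,
          limit: float | None = None, zero_velocities: bool = False):
    """Iterate Verlet steps until the average pressure stabilises.

    Convergence: the relative spread of the pressure over a sliding
    *window* of steps falls below *pressure_tol* (pressures below
    *pressure_floor* count as zero).  Returns ``(steps, P_final)``;
    emits no error on hitting *max_steps* (the state is still returned).

    *zero_velocities* starts from rest (quasi-static relaxation between
    biological steps); *limit* caps the per-step displacement, see
    :func:`verlet_step`.
    """
    if len(pop) == 0:
        return 0, 0.0
    if zero_velocities:
        pop.velocity[...] = 0.0
    if cutoff is None:
        cutoff = params.adhesion_cutoff * float(pop.outer_diameter.max())
    if skin is None:
        skin = 0.5 * float(pop.radius.min())
    nlist = build_neighbor_list(pop, domain, cutoff, skin)
    F, virial = compute_forces(pop, domain, params, nlist, grid, velocity_field)
    pop.force = F
    P = average_pressure(pop, virial)
    if abs(P) < pressure_floor and float(np.abs(F).max(initial=0.0)) == 0.0:
        return 0, P  # already at rest and force-free
    history = [P]
    for step in range(1, max_steps + 1):
        virial = verlet_step(pop, domain, params, nlist, dt, grid, velocity_field,
                             limit=limit)
        P = average_pressure(pop, virial)
        history.append(P)
        if len(history) > window:
            history.pop(0)
            lo, hi = min(history), max(history)
            scale = max(abs(lo), abs(hi), pressure_floor)
            if (hi - lo) / scale < pressure_tol or scale <= pressure_floor:
                return step, P
    return max_steps, P
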