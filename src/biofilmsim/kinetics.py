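"""Growth kinetics: Monod-based and energy-based specific growth rates, and
the mapping from agent growth to per-voxel solute reaction rates.

Monod model
-----------
Each functional group carries one or more metabolic pathways.  Pathway *p*
contributes

    mu_p = mu_max * eta_p * prod_s  S_s / (K_{p,s} + S_s) * prod_s' K_I/(K_I + S_s')

evaluated at the concentrations of the voxel the agent resides in (eta is 1
for aerobic pathways and the anoxic reduction factor etaHET for
denitrification; the optional second product holds inhibition terms, e.g.
oxygen inhibition of anoxic growth).  The net specific growth rate is
``sum_p mu_p - b`` with first-order decay rate *b*.

Energy model
------------
The growth rate is set by the harvested metabolic energy,

    mu = Y * (q_met - m_req),

and the per-solute rates follow the overall growth reaction,

    R = mu * (Cat / Y + Ana) * X,

with catabolic (Cat) and anabolic (Ana) free energies per unit biomass,
biomass density X, and yield Y precomputed by the energy-dissipation method.
q_met saturates Monod-style on the *active* (non-charged) substrate forms
supplied by the pH module when enabled.

Reaction accumulation
---------------------
The voxel reaction field is R[v, s] = sum_{i in v} sum_p nu[g_i, p, s] *
mu_{p,i} * m_i / V_voxel (consumption negative).  Because kinetic parameters
are shared within a group, the sum only depends on the per-voxel biomass of
each group; :func:`voxel_reaction_rates` exploits that, and
:func:`accumulate_voxel_reactions` is the literal per-agent sum kept for
cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .agents import FunctionalGroup, Population
from .domain import Grid, locate_voxel

__all__ = [
    "monod_growth_rate",
    "EnergyGroup",
    "energy_growth_rate",
    "energy_metabolic_rate",
    "energy_reaction_rate",
    "accumulate_voxel_reactions",
    "voxel_reaction_rates",
    "assign_growth_rates",
]


def _pathway_rates(group: FunctionalGroup, conc: dict) -> dict:
    """Per-pathway specific rates mu_p (s^-1) at the given concentrations."""
    rates = {}
    for p in group.pathways:
        mu_p = group.mu_max * p.eta
        for s, K in p.monod.items():
            if s not in conc:
                raise KeyError(f"pathway {group.name}/{p.name} needs solute {s!r} "
                               "which is not configured")
            S = max(float(conc[s]), 0.0)
            mu_p *= S / (K + S)
        for s, KI in p.inhibition.items():
            S = max(float(conc.get(s, 0.0)), 0.0)
            mu_p *= KI / (KI + S)
        rates[p.name] = mu_p
    return rates


def monod_growth_rate(group: FunctionalGroup, local_conc: dict):
    """Net Monod growth rate and per-pathway weights at local concentrations.

    Returns ``(mu, weights)`` where ``mu = sum_p mu_p - b`` and *weights*
    maps pathway name to its mu_p, used to split the reaction stoichiometry.
    """
    weights = _pathway_rates(group, local_conc)
    mu = sum(weights.values()) - group.decay_rate
    return mu, weights


# -- energy-based model ------------------------------------------------------


@dataclass
class EnergyGroup:
    """Energy-model parameters of one functional group.

    ``cat``/``ana`` are catabolic/anabolic free energies per unit biomass
    (config-supplied, already temperature-adjusted); ``stoich`` distributes
    the overall-reaction rate R over the solutes (signed weights).
    """

    name: str
    yield_: float
    q_max: float  # maximum metabolic rate, s^-1
    m_req: float = 0.0  # maintenance requirement, s^-1
    cat: float = 0.0
    ana: float = 0.0
    monod: dict = field(default_factory=dict)  # solute -> K on the active form
    stoich: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.m_req < 0:
            raise ValueError("maintenance requirement must be >= 0")
        if not np.isfinite(self.cat) or not np.isfinite(self.ana):
            raise ValueError("Cat/Ana free energies must be finite")


def energy_metabolic_rate(model: EnergyGroup, active_conc: dict) -> float:
    """Metabolic rate q_met: q_max saturating on the active substrate forms."""
    q = model.q_max
    for s, K in model.monod.items():
        S = max(float(active_conc.get(s, 0.0)), 0.0)
        q *= S / (K + S)
    return q


def energy_growth_rate(model: EnergyGroup, q_met: float) -> float:
    """mu = Y (q_met - m_req); negative when maintenance is unmet."""
    if q_met < 0:
        raise ValueError("metabolic rate must be >= 0")
    return model.yield_ * (q_met - model.m_req)


def energy_reaction_rate(model: EnergyGroup, mu: float, X: float):
    """Overall reaction rate R = mu (Cat/Y + Ana) X, split over solutes.

    Returns ``(R_total, per_solute)`` with X the biomass density (kg m^-3).
    """
    if X < 0:
        raise ValueError("biomass density must be >= 0")
    R = mu * (model.cat / model.yield_ + model.ana) * X
    return R, {s: R * w for s, w in model.stoich.items()}


# -- voxel reaction accumulation --------------------------------------------


def accumulate_voxel_reactions(pop: Population, grid: Grid, fields: dict) -> dict:
    """Literal per-agent reaction sum; reference implementation.

    *fields* maps solute name -> (nx, ny, nz) concentration array.  Returns
    solute name -> reaction-rate array (kg m^-3 s^-1), including growth
    pathways and first-order decay stoichiometry of biotic groups.
    """
    R = {s: grid.zeros() for s in fields}
    if len(pop) == 0:
        return R
    Vv = grid.voxel_volume
    idx = locate_voxel(grid, pop.position)
    for i in range(len(pop)):
        g = pop.group_of(i)
        v = tuple(idx[i])
        if g.biotic:
            conc = {s: fields[s][v] for s in fields}
            weights = _pathway_rates(g, conc)
            for p in g.pathways:
                mu_p = weights[p.name]
                for s, nu in p.stoich.items():
                    R[s][v] += nu * mu_p * pop.mass[i] / Vv
        # decay stoichiometry also covers lysis of DEAD agents
        for s, nu in g.decay_stoich.items():
            R[s][v] += nu * g.decay_rate * pop.mass[i] / Vv
    return R


def _group_biomass_per_voxel(pop: Population, grid: Grid) -> np.ndarray:
    """Biomass (kg) of each group in each voxel, shape (n_groups, nx, ny, nz)."""
    B = np.zeros((len(pop.groups),) + grid.shape)
    if len(pop) == 0:
        return B
    idx = locate_voxel(grid, pop.position)
    np.add.at(B, (pop.group, idx[:, 0], idx[:, 1], idx[:, 2]), pop.mass)
    return B


def _vector_pathway_rates(group: FunctionalGroup, fields: dict) -> dict:
    out = {}
    for p in group.pathways:
        mu_p = np.full(next(iter(fields.values())).shape, group.mu_max * p.eta)
        for s, K in p.monod.items():
            S = np.maximum(fields[s], 0.0)
            mu_p = mu_p * (S / (K + S))
        for s, KI in p.inhibition.items():
            S = np.maximum(fields[s], 0.0)
            mu_p = mu_p * (KI / (KI + S))
        out[p.name] = mu_p
    return out


def voxel_reaction_rates(pop: Population, grid: Grid, fields: dict,
                         biomass=None) -> dict:
    """Vectorised voxel reaction field, identical to the per-agent sum.

    *biomass* may pass a precomputed :func:`_group_biomass_per_voxel` array
    so that a steady-state solve does not re-bin agents every sweep (agent
    masses are frozen within a biological step).
    """
    if biomass is None:
        biomass = _group_biomass_per_voxel(pop, grid)
    Vv = grid.voxel_volume
    R = {s: grid.zeros() for s in fields}
    for gi, g in enumerate(pop.groups):
        if not np.any(biomass[gi]):
            continue
        X = biomass[gi] / Vv  # kg m^-3 of this group per voxel
        if g.biotic:
            rates = _vector_pathway_rates(g, fields)
            for p in g.pathways:
                mu_p = rates[p.name]
                for s, nu in p.stoich.items():
                    R[s] += nu * mu_p * X
        for s, nu in g.decay_stoich.items():
            R[s] += nu * g.decay_rate * X
    return R


def assign_growth_rates(pop: Population, grid: Grid, fields: dict) -> None:
    """Set each agent's net growth rate from its voxel's (frozen) solute field."""
    if len(pop) == 0:
        return
    idx = locate_voxel(grid, pop.position)
    mu = np.zeros(len(pop))
    for gi, g in enumerate(pop.groups):
        sel = pop.group == gi
        if not np.any(sel):
            continue
        if not g.biotic:
            # EPS is inert; DEAD shrinks by first-order lysis (decay_rate)
            mu[sel] = -g.decay_rate
            continue
        rates = _vector_pathway_rates(g, fields)
        if rates:
            mu_g = sum(rates.values()) - g.decay_rate
            ii = idx[sel]
            mu[sel] = np.asarray(mu_g)[ii[:, 0], ii[:, 1], ii[:, 2]]
        else:
            mu[sel] = -g.decay_rate
    pop.growth_rate = mu
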