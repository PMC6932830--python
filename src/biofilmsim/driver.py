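"""The simulation loop: frozen-state coupling of biology, chemistry and
mechanics.

Each biological step runs, in order:

1. prescribed fluid velocity / drag inputs refreshed,
2. solute fields iterated to pseudo steady state against the *frozen*
   biomass distribution (with per-voxel pH speciation and gas-liquid
   transfer when the energy-based model is configured),
3. chemostat update of the bulk concentrations from the converged
   reaction field,
4. growth integration of every agent against the frozen solute field,
5. instantaneous events: division, death/removal, EPS excretion,
6. mechanical relaxation (DEM) to restore force equilibrium,
7. region relabelling and neighbour-list upkeep.

Processes are enabled individually ("fixes"); a disabled stage is skipped
without perturbing the others.  All randomness flows through one seeded
generator, so a fixed seed reproduces the trajectory bit for bit.
"""

from __future__ import annotations

import logging
import os

import numpy as np

from . import io as sio
from .agents import (DEAD, REMOVE, Population, death_status, divide,
                     eps_excrete, integrate_growth)
from .chemistry import bulk_update, gas_liquid_rates, solve_ph, solve_to_steady_state
from .config import SimConfig, parse_config, serialise_config
from .domain import build_grid, update_regions
from .kinetics import (_group_biomass_per_voxel, assign_growth_rates,
                       voxel_reaction_rates)
from .mechanics import relax
from .observables import TimeSeriesWriter, height_map, roughness
from .domain import locate_voxel

__all__ = ["Simulation", "StageError"]

log = logging.getLogger("biofilmsim")


class StageError(RuntimeError):
    """A simulation stage failed; carries the stage name and step index."""

    def __init__(self, stage, step, cause):
        super().__init__(f"stage {stage!r} failed at biological step {step}: {cause}")
        self.stage = stage
        self.step = step
        self.__cause__ = cause


class Simulation:
    """Owns the full mutable state of one run."""

    def __init__(self, config: SimConfig, pop: Population | None = None,
                 velocity_field: np.ndarray | None = None,
                 config_text: str | None = None):
        self.config = config
        self.grid = build_grid(config.domain, config.voxel_size)
        self.pop = pop if pop is not None else Population(config.groups)
        self.fields = {name: np.full(self.grid.shape, spec.s_bulk)
                       for name, spec in config.solutes.items()}
        self.bulk = config.bulk
        self.bulk.s_bulk = {name: spec.s_bulk for name, spec in config.solutes.items()}
        self.gas_headspace = {name: spec.gas.s_gas
                              for name, spec in config.solutes.items() if spec.gas}
        self.velocity_field = velocity_field
        self.rng = np.random.default_rng(config.run.seed)
        self.time = 0.0
        self.step = 0
        self.config_text = config_text if config_text is not None else serialise_config(config)
        self.last_reaction = {}
        self.last_solver_iters = 0
        self.last_pressure = 0.0
        self.ph_field = None
        update_regions(self.grid, self.pop, config.region)

    # -- construction from a restart file -----------------------------------

    @classmethod
    def from_restart(cls, path, config: SimConfig | None = None,
                     velocity_field=None) -> "Simulation":
        state = sio.read_restart(path)
        if config is None:
            config = parse_config(state["config_text"])
        sim = cls(config, velocity_field=velocity_field,
                  config_text=state["config_text"])
        pop = Population(config.groups)
        names = state["particles_attrs"]["group_names"]
        if names != [g.name for g in config.groups]:
            raise sio.RestartError("functional groups of restart and config differ")
        for key, val in state["particles_raw"].items():
            setattr(pop, key, val)
        pop.group = pop.group.astype(np.int32)
        pop._next_id = state["particles_attrs"]["next_id"]
        sim.pop = pop
        sim.fields = dict(state["fields"])
        sim.bulk.s_bulk = dict(state["s_bulk"])
        sim.gas_headspace = dict(state["s_gas"])
        sim.rng.bit_generator.state = state["rng_state"]
        sim.time = state["time"]
        sim.step = state["step"]
        update_regions(sim.grid, sim.pop, config.region)
        return sim

    def write_restart(self, path):
        sio.write_restart(path, self)

    # -- chemistry helpers ---------------------------------------------------

    def _ph_speciation_fractions(self):
        """Per-voxel neutral-form fraction of each pH-coupled solute.

        Solved once per biological step and frozen through the steady-state
        sweep (the charge balance is quasi-instantaneous relative to
        transport, and its drift within one step is second order).
        """
        cfg = self.config
        if cfg.acid_base is None:
            return None
        linked = {name: spec for name, spec in cfg.solutes.items()
                  if spec.acid_base and spec.molar_mass}
        if not linked:
            return None
        shape = self.grid.shape
        ph = np.zeros(shape)
        alpha = {name: np.ones(shape) for name in linked}
        it = np.ndindex(shape)
        for v in it:
            totals = {}
            for name, spec in linked.items():
                mol_per_L = self.fields[name][v] / spec.molar_mass / 1000.0
                totals[spec.acid_base] = totals.get(spec.acid_base, 0.0) + mol_per_L
            h, spec_out = solve_ph(totals, cfg.acid_base)
            ph[v] = -np.log10(h)
            for name, spec in linked.items():
                sp = cfg.acid_base.species[spec.acid_base]
                forms = spec_out[spec.acid_base]
                total = float(np.sum(forms))
                if total <= 0 or not hasattr(sp, "charges"):
                    continue
                neutral = np.flatnonzero(sp.charges() == 0)
                alpha[name][v] = float(forms[neutral].sum() / total) if neutral.size else 1.0
        self.ph_field = ph
        return alpha

    def _reaction_callback(self, biomass, alpha=None):
        cfg = self.config

        def callback(fields):
            if cfg.growth_model == "energy" and cfg.energy:
                R = self._energy_rates(fields, biomass, alpha)
            else:
                R = voxel_reaction_rates(self.pop, self.grid, fields, biomass=biomass)
            # gas-liquid transfer into the liquid reaction term
            for name, spec in cfg.solutes.items():
                if spec.gas is not None:
                    gas = spec.gas
                    s_gas = self.gas_headspace[name]
                    R[name] = R.get(name, self.grid.zeros()) + gas.kla * (
                        s_gas - fields[name] / gas.henry)
            return R

        return callback

    def _energy_rates(self, fields, biomass, alpha):
        """Energy-model reaction field: R = mu (Cat/Y + Ana) X per group."""
        cfg = self.config
        Vv = self.grid.voxel_volume
        R = {s: self.grid.zeros() for s in fields}
        for gi, g in enumerate(cfg.groups):
            e = cfg.energy.get(g.name)
            if e is None or not np.any(biomass[gi]):
                continue
            X = biomass[gi] / Vv
            q = np.full(self.grid.shape, e.q_max)
            for s, K in e.monod.items():
                S = np.maximum(fields[s], 0.0)
                if alpha is not None and s in alpha:
                    S = S * alpha[s]
                q *= S / (K + S)
            mu = e.yield_ * (q - e.m_req)
            R_total = mu * (e.cat / e.yield_ + e.ana) * X
            for s, w in e.stoich.items():
                R[s] += w * R_total
        return R

    def _assign_energy_growth(self, alpha):
        cfg = self.config
        idx = locate_voxel(self.grid, self.pop.position) if len(self.pop) else None
        mu = np.zeros(len(self.pop))
        for gi, g in enumerate(cfg.groups):
            sel = self.pop.group == gi
            if not np.any(sel):
                continue
            e = cfg.energy.get(g.name)
            if e is None:
                mu[sel] = -g.decay_rate if not g.biotic else 0.0
                continue
            q = np.full(self.grid.shape, e.q_max)
            for s, K in e.monod.items():
                S = np.maximum(self.fields[s], 0.0)
                if alpha is not None and s in alpha:
                    S = S * alpha[s]
                q *= S / (K + S)
            mu_g = e.yield_ * (q - e.m_req)
            ii = idx[sel]
            mu[sel] = mu_g[ii[:, 0], ii[:, 1], ii[:, 2]]
        self.pop.growth_rate = mu
        return mu

    # -- the biological step --------------------------------------------------

    def bio_step(self):
        cfg = self.config
        enabled = set(cfg.processes)
        dt_bio = cfg.timesteps.bio
        alpha = None

        def _stage(name, fn):
            try:
                return fn()
            except Exception as e:
                raise StageError(name, self.step, e) from e

        # (1-2) velocity field is prescribed & static; solve solutes to steady state
        if "mass_balance" in enabled and self.fields:
            def solve():
                nonlocal alpha
                biomass = _group_biomass_per_voxel(self.pop, self.grid)
                if cfg.growth_model == "energy":
                    alpha = self._ph_speciation_fractions()
                cb = self._reaction_callback(biomass, alpha)
                iters = solve_to_steady_state(
                    self.grid, self.fields, cfg.solutes, self.bulk.s_bulk,
                    R_callback=cb, velocity=self.velocity_field,
                    dt=cfg.timesteps.diffusion, tol=cfg.diffusion_tol,
                    max_iters=cfg.diffusion_max_iters)
                self.last_solver_iters = iters
                self.last_reaction = cb(self.fields)
                # headspace balance from the domain-mean liquid concentration
                T = cfg.acid_base.temperature if cfg.acid_base else 298.15
                for name, spec in cfg.solutes.items():
                    if spec.gas is not None:
                        gas = spec.gas
                        gas.s_gas = self.gas_headspace[name]
                        s_liq = float(np.mean(self.fields[name]))
                        _, r_lg = gas_liquid_rates(gas, s_liq,
                                                   self.grid.domain.volume, T)
                        self.gas_headspace[name] = max(
                            0.0, self.gas_headspace[name] + dt_bio * r_lg)
            _stage("mass_balance", solve)

        # (3) bulk chemostat balance
        if "bulk" in enabled:
            _stage("bulk", lambda: bulk_update(
                self.bulk, cfg.solutes, self.last_reaction, self.grid, dt_bio))

        # (4) growth
        if "growth" in enabled and len(self.pop):
            def grow():
                if cfg.growth_model == "energy" and cfg.energy:
                    self._assign_energy_growth(alpha)
                else:
                    assign_growth_rates(self.pop, self.grid, self.fields)
                integrate_growth(self.pop, dt_bio)
            _stage("growth", grow)

        # (5) instantaneous events, in a deterministic order
        if "division" in enabled and len(self.pop):
            def do_divide():
                for _ in range(10):  # a single pass normally suffices
                    d = self.pop.diameter
                    thr = np.array([g.division_diameter for g in self.pop.groups])
                    t_i = thr[self.pop.group]
                    ready = np.flatnonzero((t_i > 0) & (d >= t_i))
                    if ready.size == 0:
                        return
                    for i in ready:
                        divide(self.pop, int(i), self.rng, cfg.division_distance)
            _stage("division", do_divide)

        if "eps_production" in enabled and len(self.pop):
            def do_eps():
                ratio_thr = np.array([g.shell_ratio_threshold for g in self.pop.groups])
                t_i = ratio_thr[self.pop.group]
                with np.errstate(divide="ignore", invalid="ignore"):
                    ratio = self.pop.outer_diameter / self.pop.diameter
                ready = np.flatnonzero((t_i > 0) & (ratio > t_i))
                for i in ready:
                    eps_excrete(self.pop, int(i), self.rng)
            _stage("eps_production", do_eps)

        if "death" in enabled and len(self.pop):
            def do_death():
                status = death_status(self.pop)
                removals = np.flatnonzero(status == REMOVE)
                if removals.size:
                    self.pop.remove(removals)
                    status = death_status(self.pop)
                newly_dead = np.flatnonzero(status == DEAD)
                if newly_dead.size and "DEAD" in self.pop._by_name:
                    self.pop.group[newly_dead] = self.pop.group_index("DEAD")
            _stage("death", do_death)

        # (6) mechanical relaxation
        if "mechanics" in enabled and len(self.pop):
            def do_relax():
                # quasi-static between biological steps: start from rest and
                # cap per-step travel at a tenth of the smallest core radius
                limit = 0.1 * float(self.pop.radius.min())
                steps, P = relax(
                    self.pop, cfg.domain, cfg.mechanics, cfg.timesteps.mech,
                    pressure_tol=cfg.pressure_tol, max_steps=cfg.relax_max_steps,
                    window=cfg.pressure_window, grid=self.grid,
                    velocity_field=None, limit=limit, zero_velocities=True)
                self.last_pressure = P
            _stage("mechanics", do_relax)

        # (7) regions and bookkeeping
        _stage("regions", lambda: update_regions(self.grid, self.pop, cfg.region))

        self.time += dt_bio
        self.step += 1

    # -- run loop -------------------------------------------------------------

    def run(self, until: float | None = None):
        """Advance until ``t >= t_end`` (or *until*); honours the output schedule."""
        cfg = self.config
        t_end = cfg.run.t_end if until is None else until
        writer = None
        out_dir = cfg.run.output_dir
        if cfg.run.output_every > 0 and out_dir:
            os.makedirs(out_dir, exist_ok=True)
            if "csv" in cfg.run.formats:
                writer = TimeSeriesWriter(
                    os.path.join(out_dir, "timeseries.csv"),
                    [g.name for g in cfg.groups])
                self._write_outputs(writer)
        try:
            while self.time < t_end - 1e-9:
                self.bio_step()
                per_group = self.pop.biomass_by_group()
                log.info(
                    "step %d t=%.1fs n=%d biomass=%s solver_iters=%d P=%.3e",
                    self.step, self.time, len(self.pop),
                    {k: f"{v:.3e}" for k, v in per_group.items()},
                    self.last_solver_iters, self.last_pressure)
                if (cfg.run.output_every > 0 and out_dir
                        and self.step % cfg.run.output_every == 0):
                    self._write_outputs(writer)
        finally:
            if writer is not None:
                writer.close()
        return self

    def _write_outputs(self, writer):
        cfg = self.config
        out_dir = cfg.run.output_dir
        lx, ly, _ = cfg.domain.lengths
        if writer is not None:
            writer.write(self.time, self.pop, lx, ly, self.grid.voxel_size)
        tag = f"{self.step:06d}"
        if "vtk" in cfg.run.formats:
            sio.write_vtk_particles(self.pop, os.path.join(out_dir, f"particles_{tag}.vtk"))
            if self.fields:
                sio.write_vtk_field(self.grid, self.fields,
                                    os.path.join(out_dir, f"fields_{tag}.vtk"))
        if "hdf5" in cfg.run.formats:
            sio.write_hdf5_snapshot(os.path.join(out_dir, f"snapshot_{tag}.h5"),
                                    self.pop, self.fields, self.time, self.step)

    # -- convenience observables ----------------------------------------------

    def biofilm_roughness(self) -> float:
        lx, ly, _ = self.config.domain.lengths
        return roughness(height_map(self.pop, lx, ly, self.grid.voxel_size))
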