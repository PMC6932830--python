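"""Declarative simulation configuration.

A simulation is configured by a YAML document with sections mirroring the
model's process registry ("fixes"): ``domain``, ``groups``, ``solutes``,
``bulk``, ``mechanics``, ``timesteps``, ``processes``, ``run`` and the
optional ``energy`` / ``acid_base`` sections of the energy-based growth
model.  Parsing is strict: unknown keys are rejected with their location,
defaults are filled in, and ``parse -> serialise -> parse`` is the
identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .agents import FunctionalGroup, Pathway
from .chemistry import AcidBase, AcidBaseSystem, BulkState, GasPartner, SoluteSpec, StrongIon
from .domain import Domain, RegionSpec
from .kinetics import EnergyGroup
from .mechanics import ForceParams

__all__ = ["SimConfig", "ConfigError", "parse_config", "serialise_config", "load_config"]

KNOWN_PROCESSES = (
    "mass_balance", "bulk", "growth", "division", "eps_production",
    "death", "lysis", "mechanics",
)


class ConfigError(ValueError):
    """Invalid or incomplete simulation configuration."""


def _take(d: dict, path: str, key: str, default=..., cast=None):
    if key in d:
        v = d.pop(key)
    elif default is not ...:
        v = default
    else:
        raise ConfigError(f"missing mandatory key {path}.{key}")
    if cast is not None and v is not None:
        try:
            v = cast(v)
        except (TypeError, ValueError) as e:
            raise ConfigError(f"bad value for {path}.{key}: {e}") from e
    return v


def _reject_unknown(d: dict, path: str):
    if d:
        raise ConfigError(f"unknown key(s) at {path}: {sorted(d)}")


@dataclass
class Timesteps:
    bio: float = 900.0
    diffusion: float | None = None  # None: 0.9 x FTCS stability bound
    mech: float = 1e-7

    def __post_init__(self):
        if self.diffusion is not None and not (self.mech <= self.diffusion <= self.bio):
            raise ConfigError("timesteps must satisfy mech <= diffusion <= bio")


@dataclass
class RunSettings:
    t_end: float = 0.0
    seed: int = 1
    output_every: int = 0  # biological steps; 0 disables file output
    output_dir: str | None = None
    formats: tuple = ("csv",)


@dataclass
class SimConfig:
    domain: Domain
    voxel_size: float
    region: RegionSpec
    groups: list
    solutes: dict  # name -> SoluteSpec
    bulk: BulkState
    mechanics: ForceParams
    timesteps: Timesteps
    processes: tuple
    run: RunSettings
    growth_model: str = "monod"
    energy: dict = field(default_factory=dict)  # group name -> EnergyGroup
    acid_base: AcidBaseSystem | None = None
    division_distance: str = "radius_sum"
    diffusion_tol: float = 1e-6
    diffusion_max_iters: int = 500_000
    relax_max_steps: int = 2000
    pressure_tol: float = 1e-3
    pressure_window: int = 100

    def group(self, name: str) -> FunctionalGroup:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(name)


def _parse_pathway(name, raw, path, solute_names):
    p = dict(raw or {})
    pw = Pathway(
        name=name,
        eta=_take(p, path, "eta", 1.0, float),
        monod={k: float(v) for k, v in (_take(p, path, "monod", {}) or {}).items()},
        stoich={k: float(v) for k, v in (_take(p, path, "stoich", {}) or {}).items()},
        inhibition={k: float(v) for k, v in (_take(p, path, "inhibition", {}) or {}).items()},
    )
    _reject_unknown(p, path)
    for coll, what in ((pw.monod, "monod"), (pw.stoich, "stoich"), (pw.inhibition, "inhibition")):
        for s in coll:
            if s not in solute_names:
                raise ConfigError(f"{path}.{what} references unconfigured solute {s!r}")
    return pw


def _parse_group(name, raw, solute_names):
    path = f"groups.{name}"
    g = dict(raw or {})
    pathways_raw = _take(g, path, "pathways", {}) or {}
    decay_stoich = {k: float(v) for k, v in (_take(g, path, "decay_stoich", {}) or {}).items()}
    for s in decay_stoich:
        if s not in solute_names:
            raise ConfigError(f"{path}.decay_stoich references unconfigured solute {s!r}")
    fg = FunctionalGroup(
        name=name,
        density=_take(g, path, "density", ..., float),
        division_diameter=_take(g, path, "division_diameter", 0.0, float),
        death_diameter=_take(g, path, "death_diameter", 0.0, float),
        mu_max=_take(g, path, "mu_max", 0.0, float),
        decay_rate=_take(g, path, "decay_rate", 0.0, float),
        yield_=_take(g, path, "yield", 1.0, float),
        decay_stoich=decay_stoich,
        eps_yield=_take(g, path, "eps_yield", 0.0, float),
        eps_density=_take(g, path, "eps_density", 0.0, float),
        shell_ratio_threshold=_take(g, path, "shell_ratio_threshold", 0.0, float),
        biotic=_take(g, path, "biotic", True, bool),
        adhesive=_take(g, path, "adhesive", False, bool),
    )
    fg.pathways = [
        _parse_pathway(pname, praw, f"{path}.pathways.{pname}", solute_names)
        for pname, praw in pathways_raw.items()
    ]
    _reject_unknown(g, path)
    return fg


def _parse_solute(name, raw):
    path = f"solutes.{name}"
    s = dict(raw or {})
    gas_raw = _take(s, path, "gas", None)
    gas = None
    if gas_raw is not None:
        gp = dict(gas_raw)
        gas = GasPartner(
            kla=_take(gp, f"{path}.gas", "kla", ..., float),
            henry=_take(gp, f"{path}.gas", "henry", ..., float),
            s_gas=_take(gp, f"{path}.gas", "s_gas", ..., float),
        )
        _reject_unknown(gp, f"{path}.gas")
    spec = SoluteSpec(
        name=name,
        diffusivity=_take(s, path, "diffusivity", ..., float),
        s_bulk=_take(s, path, "s_bulk", 0.0, float),
        s_in=_take(s, path, "s_in", 0.0, float),
        bc_top=_take(s, path, "bc_top", "dirichlet", str),
        fixed_bulk=_take(s, path, "fixed_bulk", False, bool),
        molar_mass=_take(s, path, "molar_mass", None, float),
        acid_base=_take(s, path, "acid_base", None, str),
        gas=gas,
    )
    _reject_unknown(s, path)
    return spec


def _parse_acid_base(raw):
    if raw is None:
        return None
    d = dict(raw)
    species = {}
    for name, sraw in (_take(d, "acid_base", "species", {}) or {}).items():
        sp = dict(sraw)
        path = f"acid_base.species.{name}"
        if "ka" in sp:
            species[name] = AcidBase(
                name=name,
                ka=tuple(float(k) for k in _take(sp, path, "ka")),
                charge0=_take(sp, path, "charge0", 0, int),
            )
        else:
            species[name] = StrongIon(name=name, charge=_take(sp, path, "charge", ..., int))
        _reject_unknown(sp, path)
    system = AcidBaseSystem(
        species=species,
        kw=_take(d, "acid_base", "kw", 1e-14, float),
        temperature=_take(d, "acid_base", "temperature", 298.15, float),
    )
    _reject_unknown(d, "acid_base")
    return system


def _parse_energy(raw, solute_names):
    out = {}
    for gname, eraw in (raw or {}).items():
        path = f"energy.{gname}"
        e = dict(eraw)
        eg = EnergyGroup(
            name=gname,
            yield_=_take(e, path, "yield", ..., float),
            q_max=_take(e, path, "q_max", ..., float),
            m_req=_take(e, path, "m_req", 0.0, float),
            cat=_take(e, path, "cat", 0.0, float),
            ana=_take(e, path, "ana", 0.0, float),
            monod={k: float(v) for k, v in (_take(e, path, "monod", {}) or {}).items()},
            stoich={k: float(v) for k, v in (_take(e, path, "stoich", {}) or {}).items()},
        )
        _reject_unknown(e, path)
        for s in list(eg.monod) + list(eg.stoich):
            if s not in solute_names:
                raise ConfigError(f"{path} references unconfigured solute {s!r}")
        out[gname] = eg
    return out


def parse_config(source) -> SimConfig:
    """Parse a YAML string (or pre-parsed mapping) into a :class:`SimConfig`."""
    if isinstance(source, str):
        raw = yaml.safe_load(source)
    else:
        raw = source
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")
    raw = dict(raw)

    dom_raw = dict(_take(raw, "<root>", "domain"))
    lengths = tuple(float(x) for x in _take(dom_raw, "domain", "lengths"))
    periodic = tuple(bool(b) for b in _take(dom_raw, "domain", "periodic", [True, True, False]))
    voxel_size = _take(dom_raw, "domain", "voxel_size", ..., float)
    layer = _take(dom_raw, "domain", "boundary_layer_height", 0.0, float)
    _reject_unknown(dom_raw, "domain")
    try:
        domain = Domain(lengths=lengths, periodic=periodic)
        region = RegionSpec(boundary_layer_height=layer)
    except ValueError as e:
        raise ConfigError(str(e)) from e

    solutes_raw = _take(raw, "<root>", "solutes", {}) or {}
    solutes = {name: _parse_solute(name, s) for name, s in solutes_raw.items()}

    groups_raw = _take(raw, "<root>", "groups", {}) or {}
    try:
        groups = [_parse_group(name, g, set(solutes)) for name, g in groups_raw.items()]
    except ValueError as e:
        raise ConfigError(str(e)) from e

    bulk_raw = dict(_take(raw, "<root>", "bulk", {}) or {})
    bulk = BulkState(
        flow_rate=_take(bulk_raw, "bulk", "flow_rate", 0.0, float),
        volume=_take(bulk_raw, "bulk", "volume", 0.0, float),
        biofilm_area=_take(bulk_raw, "bulk", "biofilm_area", 0.0, float),
        s_bulk={name: spec.s_bulk for name, spec in solutes.items()},
    )
    _reject_unknown(bulk_raw, "bulk")

    mech_raw = dict(_take(raw, "<root>", "mechanics", {}) or {})
    relax_max_steps = _take(mech_raw, "mechanics", "relax_max_steps", 2000, int)
    pressure_tol = _take(mech_raw, "mechanics", "pressure_tol", 1e-3, float)
    pressure_window = _take(mech_raw, "mechanics", "window", 100, int)
    boundary = tuple(_take(mech_raw, "mechanics", "boundary", ["wrap", "wrap", "reflect"]))
    try:
        mechanics = ForceParams(
            kn=_take(mech_raw, "mechanics", "kn", 1e-4, float),
            gamma_n=_take(mech_raw, "mechanics", "gamma_n", 1e5, float),
            hamaker=_take(mech_raw, "mechanics", "hamaker", 0.0, float),
            h_floor=_take(mech_raw, "mechanics", "h_floor", 1e-9, float),
            adhesion_cutoff=_take(mech_raw, "mechanics", "adhesion_cutoff", 1.5, float),
            fluid_viscosity=_take(mech_raw, "mechanics", "fluid_viscosity", 1e-3, float),
            fluid_density=_take(mech_raw, "mechanics", "fluid_density", 1000.0, float),
            boundary=boundary,
        )
    except ValueError as e:
        raise ConfigError(str(e)) from e
    _reject_unknown(mech_raw, "mechanics")

    ts_raw = dict(_take(raw, "<root>", "timesteps", {}) or {})
    timesteps = Timesteps(
        bio=_take(ts_raw, "timesteps", "bio", 900.0, float),
        diffusion=_take(ts_raw, "timesteps", "diffusion", None, float),
        mech=_take(ts_raw, "timesteps", "mech", 1e-7, float),
    )
    _reject_unknown(ts_raw, "timesteps")

    processes = tuple(_take(raw, "<root>", "processes", list(KNOWN_PROCESSES)))
    for p in processes:
        if p not in KNOWN_PROCESSES:
            raise ConfigError(f"processes: unknown process {p!r} "
                              f"(known: {', '.join(KNOWN_PROCESSES)})")

    run_raw = dict(_take(raw, "<root>", "run", {}) or {})
    run = RunSettings(
        t_end=_take(run_raw, "run", "t_end", 0.0, float),
        seed=_take(run_raw, "run", "seed", 1, int),
        output_every=_take(run_raw, "run", "output_every", 0, int),
        output_dir=_take(run_raw, "run", "output_dir", None, str),
        formats=tuple(_take(run_raw, "run", "formats", ["csv"])),
    )
    _reject_unknown(run_raw, "run")

    growth_model = _take(raw, "<root>", "growth_model", "monod", str)
    if growth_model not in ("monod", "energy"):
        raise ConfigError(f"growth_model must be 'monod' or 'energy', got {growth_model!r}")
    energy = _parse_energy(_take(raw, "<root>", "energy", None), set(solutes))
    acid_base = _parse_acid_base(_take(raw, "<root>", "acid_base", None))
    if growth_model == "energy" and not energy:
        raise ConfigError("growth_model 'energy' needs an energy section")

    division_distance = _take(raw, "<root>", "division_distance", "radius_sum", str)
    if division_distance not in ("radius_sum", "diameter_sum"):
        raise ConfigError("division_distance must be radius_sum or diameter_sum")

    diff_raw = dict(_take(raw, "<root>", "diffusion", {}) or {})
    diffusion_tol = _take(diff_raw, "diffusion", "tol", 1e-6, float)
    diffusion_max_iters = _take(diff_raw, "diffusion", "max_iters", 500_000, int)
    _reject_unknown(diff_raw, "diffusion")

    _reject_unknown(raw, "<root>")

    # cross-validation: Monod growth needs every referenced solute configured
    # (done at pathway parse) and a K for every Monod term (by construction)
    return SimConfig(
        domain=domain, voxel_size=voxel_size, region=region, groups=groups,
        solutes=solutes, bulk=bulk, mechanics=mechanics, timesteps=timesteps,
        processes=processes, run=run, growth_model=growth_model, energy=energy,
        acid_base=acid_base, division_distance=division_distance,
        diffusion_tol=diffusion_tol, diffusion_max_iters=diffusion_max_iters,
        relax_max_steps=relax_max_steps, pressure_tol=pressure_tol,
        pressure_window=pressure_window,
    )


def serialise_config(cfg: SimConfig) -> str:
    """YAML round-trip form of a config (parse(serialise(c)) == parse input)."""
    d: dict = {
        "domain": {
            "lengths": list(cfg.domain.lengths),
            "periodic": list(cfg.domain.periodic),
            "voxel_size": cfg.voxel_size,
            "boundary_layer_height": cfg.region.boundary_layer_height,
        },
        "solutes": {},
        "groups": {},
        "bulk": {
            "flow_rate": cfg.bulk.flow_rate,
            "volume": cfg.bulk.volume,
            "biofilm_area": cfg.bulk.biofilm_area,
        },
        "mechanics": {
            "kn": cfg.mechanics.kn, "gamma_n": cfg.mechanics.gamma_n,
            "hamaker": cfg.mechanics.hamaker, "h_floor": cfg.mechanics.h_floor,
            "adhesion_cutoff": cfg.mechanics.adhesion_cutoff,
            "fluid_viscosity": cfg.mechanics.fluid_viscosity,
            "fluid_density": cfg.mechanics.fluid_density,
            "boundary": list(cfg.mechanics.boundary),
            "relax_max_steps": cfg.relax_max_steps,
            "pressure_tol": cfg.pressure_tol,
            "window": cfg.pressure_window,
        },
        "timesteps": {"bio": cfg.timesteps.bio, "diffusion": cfg.timesteps.diffusion,
                      "mech": cfg.timesteps.mech},
        "processes": list(cfg.processes),
        "run": {"t_end": cfg.run.t_end, "seed": cfg.run.seed,
                "output_every": cfg.run.output_every,
                "output_dir": cfg.run.output_dir, "formats": list(cfg.run.formats)},
        "growth_model": cfg.growth_model,
        "division_distance": cfg.division_distance,
        "diffusion": {"tol": cfg.diffusion_tol, "max_iters": cfg.diffusion_max_iters},
    }
    for name, s in cfg.solutes.items():
        sd = {"diffusivity": s.diffusivity, "s_bulk": s.s_bulk, "s_in": s.s_in,
              "bc_top": s.bc_top, "fixed_bulk": s.fixed_bulk}
        if s.molar_mass is not None:
            sd["molar_mass"] = s.molar_mass
        if s.acid_base is not None:
            sd["acid_base"] = s.acid_base
        if s.gas is not None:
            sd["gas"] = {"kla": s.gas.kla, "henry": s.gas.henry, "s_gas": s.gas.s_gas}
        d["solutes"][name] = sd
    for g in cfg.groups:
        gd = {"density": g.density, "division_diameter": g.division_diameter,
              "death_diameter": g.death_diameter, "mu_max": g.mu_max,
              "decay_rate": g.decay_rate, "yield": g.yield_,
              "eps_yield": g.eps_yield, "eps_density": g.eps_density,
              "shell_ratio_threshold": g.shell_ratio_threshold,
              "biotic": g.biotic, "adhesive": g.adhesive,
              "decay_stoich": dict(g.decay_stoich),
              "pathways": {p.name: {"eta": p.eta, "monod": dict(p.monod),
                                    "stoich": dict(p.stoich),
                                    "inhibition": dict(p.inhibition)}
                           for p in g.pathways}}
        d["groups"][g.name] = gd
    if cfg.energy:
        d["energy"] = {name: {"yield": e.yield_, "q_max": e.q_max, "m_req": e.m_req,
                              "cat": e.cat, "ana": e.ana, "monod": dict(e.monod),
                              "stoich": dict(e.stoich)}
                       for name, e in cfg.energy.items()}
    if cfg.acid_base is not None:
        species = {}
        for name, sp in cfg.acid_base.species.items():
            if isinstance(sp, StrongIon):
                species[name] = {"charge": sp.charge}
            else:
                species[name] = {"ka": list(sp.ka), "charge0": sp.charge0}
        d["acid_base"] = {"species": species, "kw": cfg.acid_base.kw,
                          "temperature": cfg.acid_base.temperature}
    # keep insertion order: group order defines the stored group indices
    return yaml.safe_dump(d, sort_keys=False)


def load_config(path) -> SimConfig:
    with open(path) as fh:
        return parse_config(fh.read())
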