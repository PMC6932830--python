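"""Snapshot and restart I/O.

Particles are written as VTK legacy polydata (positions plus radius, outer
radius, group and velocity point data) and solute fields as VTK legacy
structured points, both ASCII — readable by ParaView and any VTK reader.
HDF5 snapshots store the full particle table and fields per timestep.
Restart files capture the complete simulation state (particles, fields,
bulk state, RNG state, clocks) so a split run continues bit-for-bit.
"""

from __future__ import annotations

import json
import os

import h5py
import numpy as np

from .agents import Population
from .domain import Grid

__all__ = [
    "write_vtk_particles",
    "write_vtk_field",
    "write_hdf5_snapshot",
    "read_hdf5_snapshot",
    "RESTART_VERSION",
    "write_restart",
    "read_restart",
    "RestartError",
]

RESTART_VERSION = 1


class RestartError(RuntimeError):
    """Unreadable, corrupted or version-incompatible restart file."""


# -- VTK legacy ASCII --------------------------------------------------------


def write_vtk_particles(pop: Population, path) -> None:
    """Particles as VTK legacy polydata: points + vertices + point data."""
    n = len(pop)
    r = pop.radius
    orad = pop.outer_radius
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("biofilmsim particles\n")
        fh.write("ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {n} double\n")
        for p in pop.position:
            fh.write(f"{p[0]:.9e} {p[1]:.9e} {p[2]:.9e}\n")
        fh.write(f"VERTICES {n} {2 * n}\n")
        for i in range(n):
            fh.write(f"1 {i}\n")
        fh.write(f"POINT_DATA {n}\n")
        fh.write("SCALARS radius double 1\nLOOKUP_TABLE default\n")
        for v in r:
            fh.write(f"{v:.9e}\n")
        fh.write("SCALARS outer_radius double 1\nLOOKUP_TABLE default\n")
        for v in orad:
            fh.write(f"{v:.9e}\n")
        fh.write("SCALARS group int 1\nLOOKUP_TABLE default\n")
        for v in pop.group:
            fh.write(f"{int(v)}\n")
        fh.write("VECTORS velocity double\n")
        for v in pop.velocity:
            fh.write(f"{v[0]:.9e} {v[1]:.9e} {v[2]:.9e}\n")


def write_vtk_field(grid: Grid, fields: dict, path) -> None:
    """Voxel fields as VTK legacy structured points (voxel-centred)."""
    nx, ny, nz = grid.shape
    dx = grid.voxel_size
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("biofilmsim solute fields\n")
        fh.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write(f"ORIGIN {dx / 2:.9e} {dx / 2:.9e} {dx / 2:.9e}\n")
        fh.write(f"SPACING {dx:.9e} {dx:.9e} {dx:.9e}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        for name, arr in fields.items():
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            for v in np.ravel(arr, order="F"):  # VTK: x varies fastest
                fh.write(f"{v:.9e}\n")


# -- HDF5 --------------------------------------------------------------------

_PARTICLE_KEYS = ("id", "group", "position", "velocity", "force", "mass",
                  "density", "outer_mass", "growth_rate")


def _write_population(h5grp, pop: Population):
    for key in _PARTICLE_KEYS:
        h5grp.create_dataset(key, data=getattr(pop, key))
    h5grp.attrs["next_id"] = pop._next_id
    h5grp.attrs["group_names"] = json.dumps([g.name for g in pop.groups])


def _read_population(h5grp, groups) -> Population:
    names = json.loads(h5grp.attrs["group_names"])
    by_name = {g.name: g for g in groups}
    pop = Population([by_name[n] for n in names])
    for key in _PARTICLE_KEYS:
        setattr(pop, key, h5grp[key][()])
    pop.group = pop.group.astype(np.int32)
    pop._next_id = int(h5grp.attrs["next_id"])
    return pop


def write_hdf5_snapshot(path, pop: Population, fields: dict | None = None,
                        time: float = 0.0, step: int = 0) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["time"] = time
        f.attrs["step"] = step
        _write_population(f.create_group("particles"), pop)
        if fields:
            g = f.create_group("fields")
            for name, arr in fields.items():
                g.create_dataset(name, data=arr)


def read_hdf5_snapshot(path, groups):
    with h5py.File(path, "r") as f:
        pop = _read_population(f["particles"], groups)
        fields = {}
        if "fields" in f:
            fields = {name: f["fields"][name][()] for name in f["fields"]}
        return pop, fields, float(f.attrs["time"]), int(f.attrs["step"])


def write_restart(path, sim) -> None:
    """Full simulation state, including the RNG, for bit-exact continuation."""
    tmp = str(path) + ".tmp"
    with h5py.File(tmp, "w") as f:
        f.attrs["restart_version"] = RESTART_VERSION
        f.attrs["time"] = sim.time
        f.attrs["step"] = sim.step
        f.attrs["rng_state"] = json.dumps(sim.rng.bit_generator.state)
        f.attrs["config"] = sim.config_text
        _write_population(f.create_group("particles"), sim.pop)
        g = f.create_group("fields")
        for name, arr in sim.fields.items():
            g.create_dataset(name, data=arr)
        f.attrs["s_bulk"] = json.dumps(sim.bulk.s_bulk)
        f.attrs["s_gas"] = json.dumps(sim.gas_headspace)
    os.replace(tmp, path)


def read_restart(path):
    """Returns a dict of restored state; raises RestartError on any defect."""
    try:
        with h5py.File(path, "r") as f:
            version = int(f.attrs.get("restart_version", -1))
            if version != RESTART_VERSION:
                raise RestartError(
                    f"restart version mismatch: file has {version}, "
                    f"expected {RESTART_VERSION}"
                )
            state = {
                "time": float(f.attrs["time"]),
                "step": int(f.attrs["step"]),
                "rng_state": json.loads(f.attrs["rng_state"]),
                "config_text": str(f.attrs["config"]),
                "s_bulk": json.loads(f.attrs["s_bulk"]),
                "s_gas": json.loads(f.attrs["s_gas"]),
                "fields": {name: f["fields"][name][()] for name in f["fields"]},
                "particles_raw": {k: f["particles"][k][()] for k in _PARTICLE_KEYS},
                "particles_attrs": {
                    "next_id": int(f["particles"].attrs["next_id"]),
                    "group_names": json.loads(f["particles"].attrs["group_names"]),
                },
            }
        return state
    except RestartError:
        raise
    except Exception as e:  # corrupted / truncated / not HDF5
        raise RestartError(f"cannot read restart file {path}: {e}") from e
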