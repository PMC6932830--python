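"""Computational domain, uniform voxel grid, and region decomposition.

The simulation domain is a 3D rectangular box ``Lx x Ly x Lz`` discretised
into cubic voxels on a uniform Cartesian grid.  Solute concentrations are
stored at voxel centres.  The box is split dynamically into three layered
regions: the *biofilm* region (occupied by agents and their EPS), a
diffusion *boundary layer* of user-set height above the highest agent, and
the perfectly mixed *bulk liquid* above that.

All quantities are SI (m, kg, s); concentrations are kg m^-3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BIOFILM",
    "BOUNDARY_LAYER",
    "BULK",
    "Domain",
    "Grid",
    "RegionSpec",
    "ConfigurationError",
    "OutOfDomainError",
    "build_grid",
    "locate_voxel",
    "update_regions",
]

# region labels, layered bottom-up
BIOFILM = 0
BOUNDARY_LAYER = 1
BULK = 2


class ConfigurationError(ValueError):
    """Raised for invalid domain/grid configuration."""


class OutOfDomainError(ValueError):
    """Raised when a position lies outside a fixed-boundary face."""


@dataclass(frozen=True)
class Domain:
    """Rectangular box with per-axis boundary style.

    ``periodic`` applies to a face *pair*; the substratum is always the
    bottom face (z = 0).
    """

    lengths: tuple[float, float, float]
    periodic: tuple[bool, bool, bool] = (True, True, False)

    def __post_init__(self):
        if len(self.lengths) != 3 or any(L <= 0 for L in self.lengths):
            raise ConfigurationError(f"domain lengths must be positive, got {self.lengths}")
        if self.periodic[2]:
            raise ConfigurationError("z axis cannot be periodic: the bottom face is the substratum")

    @property
    def volume(self) -> float:
        Lx, Ly, Lz = self.lengths
        return Lx * Ly * Lz

    def wrap(self, pos: np.ndarray) -> np.ndarray:
        """Wrap positions onto periodic axes (no-op on fixed axes)."""
        pos = np.array(pos, dtype=float, copy=True)
        p = np.atleast_2d(pos)
        for ax in range(3):
            if self.periodic[ax]:
                p[:, ax] %= self.lengths[ax]
        return p.reshape(np.shape(pos))

    def min_image(self, dx: np.ndarray) -> np.ndarray:
        """Apply the minimum-image convention to displacement vectors."""
        dx = np.array(dx, dtype=float, copy=True)
        d = np.atleast_2d(dx)
        for ax in range(3):
            if self.periodic[ax]:
                L = self.lengths[ax]
                d[:, ax] -= L * np.round(d[:, ax] / L)
        return d.reshape(np.shape(dx))


@dataclass(frozen=True)
class RegionSpec:
    """Boundary-layer height (m) measured up from the maximum biofilm thickness."""

    boundary_layer_height: float = 0.0

    def __post_init__(self):
        if self.boundary_layer_height < 0:
            raise ConfigurationError("boundary layer height must be >= 0")


@dataclass
class Grid:
    """Uniform cubic-voxel grid over a :class:`Domain`.

    Voxel ``(i, j, k)`` covers the half-open box
    ``[i*dx, (i+1)*dx) x ... `` with its centre at ``((i+.5)dx, ...)``.
    """

    domain: Domain
    voxel_size: float
    shape: tuple[int, int, int]
    regions: np.ndarray = field(repr=False)

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    @property
    def voxel_volume(self) -> float:
        return self.voxel_size**3

    def centers(self, axis: int) -> np.ndarray:
        """Voxel-centre coordinates along one axis."""
        n = self.shape[axis]
        return (np.arange(n) + 0.5) * self.voxel_size

    def zeros(self) -> np.ndarray:
        return np.zeros(self.shape)


def build_grid(domain: Domain, voxel_size: float) -> Grid:
    """Discretise *domain* into cubic voxels of edge *voxel_size*.

    Each domain length must be an integer multiple of the voxel size
    (relative tolerance 1e-9).  All region labels start as BULK.
    """
    if voxel_size <= 0:
        raise ConfigurationError(f"voxel size must be positive, got {voxel_size}")
    shape = []
    for ax, name in enumerate("xyz"):
        L = domain.lengths[ax]
        n = L / voxel_size
        n_round = round(n)
        if n_round == 0 or abs(n - n_round) > 1e-9 * max(1.0, n):
            raise ConfigurationError(
                f"domain length L{name}={L} is not divisible by voxel size {voxel_size}"
            )
        shape.append(int(n_round))
    shape = tuple(shape)
    regions = np.full(shape, BULK, dtype=np.int8)
    return Grid(domain=domain, voxel_size=voxel_size, shape=shape, regions=regions)


def locate_voxel(grid: Grid, position) -> tuple:
    """Voxel index (i, j, k) containing *position*.

    Positions are wrapped on periodic axes first; on fixed axes a position
    outside the box raises :class:`OutOfDomainError`.  Voxels are half-open,
    so a point exactly on an interior voxel face belongs to the upper voxel;
    the index is clamped so the far domain face maps to the last voxel.
    """
    pos = np.asarray(position, dtype=float)
    single = pos.ndim == 1
    p = np.atleast_2d(pos).copy()
    for ax in range(3):
        L = grid.domain.lengths[ax]
        if grid.domain.periodic[ax]:
            p[:, ax] %= L
        else:
            bad = (p[:, ax] < 0) | (p[:, ax] > L)
            if np.any(bad):
                raise OutOfDomainError(
                    f"position outside fixed boundary on axis {'xyz'[ax]}: "
                    f"{p[bad][0].tolist()}"
                )
    idx = np.floor(p / grid.voxel_size).astype(int)
    idx = np.clip(idx, 0, np.array(grid.shape) - 1)
    if single:
        return tuple(int(v) for v in idx[0])
    return idx


def update_regions(grid: Grid, particles, spec: RegionSpec) -> Grid:
    """Relabel voxels as BIOFILM / BOUNDARY_LAYER / BULK in place.

    The biofilm thickness H is the maximum of ``z + outer radius`` over all
    particles (0 with no particles); the biofilm/boundary interface is
    snapped *up* to the next voxel boundary so regions conform to whole
    voxels.  The boundary layer spans the configured height above that,
    likewise snapped; everything above is bulk.
    """
    dx = grid.voxel_size
    Lz = grid.domain.lengths[2]
    if particles is not None and len(particles) > 0:
        z_top = particles.position[:, 2] + 0.5 * particles.outer_diameter
        H = float(max(0.0, z_top.max()))
    else:
        H = 0.0
    if H + spec.boundary_layer_height > Lz:
        warnings.warn(
            "biofilm + boundary layer exceed the domain height; bulk region may be empty",
            stacklevel=2,
        )
    # snap interfaces up to voxel boundaries
    k_bio = int(np.ceil(H / dx - 1e-12))
    k_bl = int(np.ceil((H + spec.boundary_layer_height) / dx - 1e-12))
    nz = grid.shape[2]
    k_bio = min(k_bio, nz)
    k_bl = min(max(k_bl, k_bio), nz)
    kk = np.arange(nz)
    labels = np.where(kk < k_bio, BIOFILM, np.where(kk < k_bl, BOUNDARY_LAYER, BULK))
    grid.regions[...] = labels[np.newaxis, np.newaxis, :]
    return grid
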