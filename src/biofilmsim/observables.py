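"""Morphology and summary statistics of the simulated community.

The biofilm surface is summarised on a 2D height map h(x, y): the top of
the highest (outer) sphere whose centre falls in each surface bin.  From it
follow the average height and the surface roughness

    roughness = sqrt( 1/(Lx Ly) Integral (h - hbar)^2 dx dy ),

evaluated as bin sums.  Floc geometry is summarised by the equivalent
diameter (sphere of equal total volume) and a box-counting fractal
dimension.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .agents import Population

__all__ = [
    "HeightMap",
    "height_map",
    "average_height",
    "roughness",
    "area_density",
    "floc_stats",
    "TimeSeriesWriter",
]


@dataclass
class HeightMap:
    """Biofilm height per (x, y) surface bin, metres."""

    heights: np.ndarray  # (nbx, nby)
    bin_size: float
    lengths: tuple  # (Lx, Ly)


def height_map(pop: Population, lx: float, ly: float, bin_size: float) -> HeightMap:
    """Max of (z + outer radius) over particles per surface bin; 0 if empty."""
    for L, name in ((lx, "Lx"), (ly, "Ly")):
        n = L / bin_size
        if abs(n - round(n)) > 1e-9 * max(1.0, n):
            raise ValueError(f"bin size {bin_size} does not divide {name}={L}")
    nbx, nby = round(lx / bin_size), round(ly / bin_size)
    h = np.zeros((nbx, nby))
    if len(pop):
        ix = np.clip((pop.position[:, 0] % lx / bin_size).astype(int), 0, nbx - 1)
        iy = np.clip((pop.position[:, 1] % ly / bin_size).astype(int), 0, nby - 1)
        top = pop.position[:, 2] + pop.outer_radius
        np.maximum.at(h, (ix, iy), top)
    return HeightMap(heights=h, bin_size=bin_size, lengths=(lx, ly))


def average_height(hmap: HeightMap) -> float:
    return float(hmap.heights.mean())


def roughness(hmap: HeightMap) -> float:
    """Population standard deviation of the bin heights (m)."""
    h = hmap.heights
    return float(np.sqrt(np.mean((h - h.mean()) ** 2)))


def area_density(pop: Population, lx: float, ly: float) -> float:
    """Total biomass (core + EPS shells) per substratum area, kg m^-2."""
    return pop.total_biomass / (lx * ly)


def floc_stats(pop: Population, n_scales: int = 4):
    """Equivalent diameter and box-counting fractal dimension.

    The equivalent diameter is that of a sphere matching the summed core
    volumes.  The fractal dimension is the least-squares slope of
    log N(l) vs log 1/l over *n_scales* dyadic box sizes spanning the
    particle cloud; it is None for a single particle (undefined).
    """
    if len(pop) == 0:
        raise ValueError("floc statistics need at least one particle")
    volumes = pop.mass / pop.density
    d_eq = (6.0 * float(volumes.sum()) / np.pi) ** (1.0 / 3.0)
    if len(pop) == 1:
        return d_eq, None

    pos = pop.position
    lo = pos.min(axis=0)
    extent = float((pos.max(axis=0) - lo).max())
    if extent <= 0:
        return d_eq, None
    extent *= 1.0 + 1e-9  # keep the far corner inside the last box
    counts, sizes = [], []
    for s in range(1, n_scales + 1):
        ell = extent / 2**s
        cells = np.floor((pos - lo) / ell).astype(np.int64)
        counts.append(len(np.unique(cells, axis=0)))
        sizes.append(ell)
    slope = np.polyfit(np.log(1.0 / np.asarray(sizes)), np.log(counts), 1)[0]
    return d_eq, float(slope)


class TimeSeriesWriter:
    """Appends per-step community summaries to a CSV file."""

    def __init__(self, path, group_names):
        self.path = path
        self.group_names = list(group_names)
        self._fh = open(path, "w", newline="")
        self._writer = csv.writer(self._fh)
        self._writer.writerow(
            ["time", "n_particles", "total_biomass", "average_height",
             "roughness", "area_density"]
            + [f"biomass_{g}" for g in self.group_names]
        )

    def write(self, time: float, pop: Population, lx: float, ly: float,
              bin_size: float):
        hmap = height_map(pop, lx, ly, bin_size)
        per_group = pop.biomass_by_group()
        self._writer.writerow(
            [f"{time:.6e}", len(pop), f"{pop.total_biomass:.9e}",
             f"{average_height(hmap):.9e}", f"{roughness(hmap):.9e}",
             f"{area_density(pop, lx, ly):.9e}"]
            + [f"{per_group.get(g, 0.0):.9e}" for g in self.group_names]
        )
        self._fh.flush()

    def close(self):
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()
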