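"""Solute transport, bulk mass balance, pH speciation and gas-liquid transfer.

Transport solves the diffusion-advection-reaction equation

    dS/dt = div(D grad S) - div(v S) + R

on the voxel grid with forward Euler in time and central differences in
space (7-point Laplacian, central advection).  Boundary conditions follow
the usual biofilm setup: Dirichlet at the bulk value on the top face,
zero-flux Neumann at the substratum, periodic on periodic side faces
(zero-flux on fixed side faces).  Voxels labelled BULK are clamped to the
bulk concentration every step — the bulk liquid is perfectly mixed.

Within one biological step the field is iterated to a pseudo steady state
and then frozen; the bulk concentration itself evolves on the biological
timescale as a chemostat balance

    dS_b/dt = Q/V (S_in - S_b) + A_f/(V Lx Ly) * Integral(R dV).

pH is obtained per voxel from the charge-balance equation

    [H+] + sum_cations m [S m+] = [OH-] + sum_anions n [S n-]

where every dissociation form is a closed-form function of [H+]; the root
is found by Newton-Raphson with a bisection (Brent) fallback bracketed in
[1e-14, 1] mol/L.  Gas-liquid exchange follows two-film kinetics with a
Henry-law equilibrium.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .domain import BULK, Grid

__all__ = [
    "GasPartner",
    "SoluteSpec",
    "BulkState",
    "StrongIon",
    "AcidBase",
    "AcidBaseSystem",
    "StabilityError",
    "stable_dt",
    "diffusion_step",
    "solve_to_steady_state",
    "bulk_update",
    "solve_ph",
    "speciation_totals",
    "gas_liquid_rates",
]

R_GAS = 8.314  # J mol^-1 K^-1


class StabilityError(RuntimeError):
    """FTCS stability bound or advective CFL violated."""


@dataclass
class GasPartner:
    """Gas-phase partner of a solute: transfer coefficient and Henry constant."""

    kla: float  # mass transfer coefficient K_L a, s^-1
    henry: float  # dimensionless Henry constant K_H
    s_gas: float  # headspace concentration, same units as the liquid

    def __post_init__(self):
        if self.kla <= 0 or self.henry <= 0:
            raise ValueError("K_L a and K_H must be positive")


@dataclass
class SoluteSpec:
    """Transport parameters and boundary conditions of one solute."""

    name: str
    diffusivity: float  # m^2 s^-1
    s_bulk: float = 0.0  # initial bulk concentration, kg m^-3
    s_in: float = 0.0  # influent concentration, kg m^-3
    bc_top: str = "dirichlet"  # dirichlet (at bulk value) | neumann
    fixed_bulk: bool = False  # e.g. aerated oxygen: bulk held constant
    molar_mass: float | None = None  # kg mol^-1, for the pH solver
    acid_base: str | None = None  # name of the acid-base species, if any
    gas: GasPartner | None = None

    def __post_init__(self):
        if self.diffusivity <= 0:
            raise ValueError(f"solute {self.name}: diffusivity must be positive")
        if self.s_bulk < 0 or self.s_in < 0:
            raise ValueError(f"solute {self.name}: concentrations must be >= 0")
        if self.bc_top not in ("dirichlet", "neumann"):
            raise ValueError(f"solute {self.name}: unknown top boundary {self.bc_top!r}")


@dataclass
class BulkState:
    """Chemostat state of the macro-scale reactor the domain is embedded in."""

    flow_rate: float  # Q, m^3 s^-1
    volume: float  # V, m^3
    biofilm_area: float  # A_f, m^2
    s_bulk: dict = field(default_factory=dict)  # solute -> S_b

    def __post_init__(self):
        if min(self.flow_rate, self.volume, self.biofilm_area) < 0:
            raise ValueError("Q, V and A_f must be >= 0")


def stable_dt(grid: Grid, specs) -> float:
    """Largest forward-Euler timestep allowed by the 3D FTCS bound, x 0.9."""
    d_max = max(s.diffusivity for s in specs)
    return 0.9 * grid.voxel_size**2 / (6.0 * d_max)


def _neighbor_sums(grid: Grid, S: np.ndarray, spec: SoluteSpec, s_bulk: float):
    """Shifted copies of S on each axis with ghost values per the BCs."""
    per = grid.domain.periodic
    out = []
    for ax in range(3):
        if per[ax]:
            lo = np.roll(S, 1, axis=ax)
            hi = np.roll(S, -1, axis=ax)
        else:
            lo = np.empty_like(S)
            hi = np.empty_like(S)
            sl_up, sl_dn = [slice(None)] * 3, [slice(None)] * 3
            sl_up[ax], sl_dn[ax] = slice(1, None), slice(None, -1)
            lo[tuple(sl_up)] = S[tuple(sl_dn)]  # lo[i] = S[i-1]
            hi[tuple(sl_dn)] = S[tuple(sl_up)]  # hi[i] = S[i+1]
            first, last = [slice(None)] * 3, [slice(None)] * 3
            first[ax], last[ax] = 0, S.shape[ax] - 1
            first, last = tuple(first), tuple(last)
            # bottom face: zero-flux (substratum / fixed wall)
            lo[first] = S[first]
            if ax == 2 and spec.bc_top == "dirichlet":
                hi[last] = 2.0 * s_bulk - S[last]  # face value pinned at S_b
            else:
                hi[last] = S[last]
        out.append((lo, hi))
    return out


def diffusion_step(grid: Grid, S: np.ndarray, spec: SoluteSpec, s_bulk: float,
                   dt: float, velocity=None, R=None, clamp_bulk: bool = True,
                   check_stability: bool = True):
    """One FTCS step of the diffusion-advection-reaction equation.

    *velocity*, if given, is a voxel-centred (nx, ny, nz, 3) field; *R* a
    reaction-rate array (kg m^-3 s^-1).  Voxels labelled BULK are reset to
    ``s_bulk`` after the update.  Returns ``(S_new, n_floored)`` where
    *n_floored* counts voxels floored at zero concentration.
    """
    dx = grid.voxel_size
    D = spec.diffusivity
    if check_stability:
        dt_max = dx**2 / (6.0 * D)
        if dt > dt_max * (1 + 1e-12):
            raise StabilityError(
                f"dt={dt:.3e} exceeds the 3D FTCS bound dx^2/(6D)={dt_max:.3e} "
                f"for solute {spec.name}"
            )
        if velocity is not None:
            vmax = float(np.abs(velocity).max())
            if vmax * dt / dx > 1 + 1e-12:
                raise StabilityError(
                    f"advective CFL {vmax * dt / dx:.3f} > 1 for solute {spec.name}"
                )

    nbrs = _neighbor_sums(grid, S, spec, s_bulk)
    lap = -6.0 * S
    for lo, hi in nbrs:
        lap += lo + hi
    dS = D * lap / dx**2

    if velocity is not None:
        v = np.asarray(velocity)
        for ax in range(3):
            vS = v[..., ax] * S
            if grid.domain.periodic[ax]:
                vS_lo = np.roll(vS, 1, axis=ax)
                vS_hi = np.roll(vS, -1, axis=ax)
            else:
                lo, hi = nbrs[ax]
                v_lo = np.roll(v[..., ax], 1, axis=ax)
                v_hi = np.roll(v[..., ax], -1, axis=ax)
                sl = [slice(None)] * 3
                sl[ax] = 0
                v_lo[tuple(sl)] = v[..., ax][tuple(sl)]
                sl[ax] = S.shape[ax] - 1
                v_hi[tuple(sl)] = v[..., ax][tuple(sl)]
                vS_lo = v_lo * lo
                vS_hi = v_hi * hi
            dS -= (vS_hi - vS_lo) / (2.0 * dx)

    if R is not None:
        dS = dS + R

    S_new = S + dt * dS
    neg = S_new < 0
    n_floored = int(neg.sum())
    if n_floored:
        S_new[neg] = 0.0
    if clamp_bulk:
        S_new[grid.regions == BULK] = s_bulk
    return S_new, n_floored


def solve_to_steady_state(grid: Grid, fields: dict, specs: dict, s_bulk: dict,
                          R_callback=None, velocity=None, dt: float | None = None,
                          tol: float = 1e-6, max_iters: int = 200_000):
    """Iterate FTCS sweeps until the fields stop changing (pseudo steady state).

    *R_callback(fields) -> dict* is re-evaluated every sweep so the reaction
    term tracks the evolving concentrations.  Convergence: the maximum
    relative per-sweep change over all solutes and voxels falls below
    *tol*.  Returns the iteration count; the arrays in *fields* are updated
    in place.  Raises RuntimeError on non-convergence.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if dt is None:
        dt = stable_dt(grid, specs.values())
    names = list(fields)
    for it in range(1, max_iters + 1):
        R = R_callback(fields) if R_callback is not None else {}
        worst = 0.0
        for name in names:
            spec = specs[name]
            S_new, _ = diffusion_step(
                grid, fields[name], spec, s_bulk[name], dt,
                velocity=velocity, R=R.get(name), check_stability=(it == 1),
            )
            scale = max(float(np.abs(S_new).max()), 1e-300)
            change = float(np.abs(S_new - fields[name]).max()) / scale
            worst = max(worst, change)
            fields[name] = S_new
        if worst < tol:
            return it
    raise RuntimeError(
        f"steady-state solve did not converge in {max_iters} sweeps "
        f"(last relative change {worst:.3e} > tol {tol:.3e})"
    )


def bulk_update(bulk: BulkState, specs: dict, R_fields: dict, grid: Grid,
                dt_bio: float) -> BulkState:
    """Forward-Euler chemostat update of the bulk concentrations.

    dS_b/dt = Q/V (S_in - S_b) + A_f/(V Lx Ly) * sum_voxels R * V_voxel.
    Solutes flagged ``fixed_bulk`` (aerated oxygen) are skipped; results
    are floored at zero.
    """
    if dt_bio <= 0:
        raise ValueError("dt_bio must be positive")
    Lx, Ly, _ = grid.domain.lengths
    Vv = grid.voxel_volume
    for name, spec in specs.items():
        if spec.fixed_bulk:
            continue
        Sb = bulk.s_bulk.get(name, spec.s_bulk)
        dSb = 0.0
        if bulk.volume > 0:
            dSb += bulk.flow_rate / bulk.volume * (spec.s_in - Sb)
            if name in R_fields:
                total_R = float(np.sum(R_fields[name])) * Vv  # kg s^-1
                dSb += bulk.biofilm_area / (bulk.volume * Lx * Ly) * total_R
        bulk.s_bulk[name] = max(0.0, Sb + dt_bio * dSb)
    return bulk


# -- pH / charge balance -----------------------------------------------------


@dataclass
class StrongIon:
    """Fully dissociated ion contributing a fixed charge per mole."""

    name: str
    charge: int


@dataclass
class AcidBase:
    """Polyprotic acid-base system H_n A -> ... with stepwise constants Ka.

    ``charge0`` is the charge of the fully protonated form; each
    deprotonation lowers the charge by one.  Speciation fractions are the
    standard closed-form functions of [H+].
    """

    name: str
    ka: tuple  # stepwise dissociation constants, mol/L
    charge0: int = 0

    def __post_init__(self):
        if any(k <= 0 for k in self.ka):
            raise ValueError(f"{self.name}: equilibrium constants must be > 0")

    def fractions(self, h: float) -> np.ndarray:
        """Fraction of each form, index 0 = fully protonated."""
        n = len(self.ka)
        terms = np.empty(n + 1)
        terms[0] = h**n
        kprod = 1.0
        for j in range(1, n + 1):
            kprod *= self.ka[j - 1]
            terms[j] = h ** (n - j) * kprod
        return terms / terms.sum()

    def charges(self) -> np.ndarray:
        return self.charge0 - np.arange(len(self.ka) + 1)


@dataclass
class AcidBaseSystem:
    """The full acid-base description: species, water ion product, temperature."""

    species: dict = field(default_factory=dict)  # name -> StrongIon | AcidBase
    kw: float = 1e-14
    temperature: float = 298.15

    def __post_init__(self):
        if self.kw <= 0:
            raise ValueError("water ion product must be > 0")


def _charge_imbalance(h: float, totals: dict, system: AcidBaseSystem) -> float:
    f = h - system.kw / h
    for name, total in totals.items():
        if total < 0:
            raise ValueError(f"total concentration of {name} must be >= 0")
        sp = system.species[name]
        if isinstance(sp, StrongIon):
            f += sp.charge * total
        else:
            f += total * float(sp.fractions(h) @ sp.charges())
    return f


def solve_ph(totals: dict, system: AcidBaseSystem, tol: float | None = None,
             max_newton: int = 50):
    """Solve the charge balance for [H+]; returns ``([H+], speciation)``.

    *totals* maps species name to its total concentration in mol/L.
    Newton-Raphson iterates on log10[H+], falling back to Brent bisection
    on the bracket [1e-14, 1] if Newton stalls or leaves the bracket.  The
    returned speciation maps each acid-base species to the per-form
    concentration array (index 0 = fully protonated) and each strong ion to
    its total.  The final charge imbalance is below
    ``1e-12 * max(1, total ionic concentration)``.
    """
    lo, hi = 1e-14, 1.0
    scale = max(1.0, sum(abs(t) for t in totals.values()) + system.kw ** 0.5)
    if tol is None:
        tol = 1e-12 * scale

    f_lo = _charge_imbalance(lo, totals, system)
    f_hi = _charge_imbalance(hi, totals, system)
    if f_lo * f_hi > 0:
        raise ArithmeticError(
            "charge balance has no root in [1e-14, 1] mol/L for totals "
            f"{totals}: f({lo})={f_lo:.3e}, f({hi})={f_hi:.3e}"
        )

    # Newton-Raphson on x = log10 h with numerical derivative
    x = 0.5 * (np.log10(lo) + np.log10(hi))
    converged = False
    for _ in range(max_newton):
        h = 10.0**x
        f = _charge_imbalance(h, totals, system)
        if abs(f) < tol:
            converged = True
            break
        dx = 1e-7
        fp = _charge_imbalance(10.0 ** (x + dx), totals, system)
        fm = _charge_imbalance(10.0 ** (x - dx), totals, system)
        deriv = (fp - fm) / (2 * dx)
        if deriv == 0:
            break
        x_new = x - f / deriv
        if not np.log10(lo) <= x_new <= np.log10(hi):
            break
        x = x_new
    if not converged:
        h = brentq(_charge_imbalance, lo, hi, args=(totals, system),
                   xtol=1e-300, rtol=8.9e-16)
        # polish: brentq terminates on interval width, verify residual
        if abs(_charge_imbalance(h, totals, system)) >= tol:
            raise ArithmeticError("pH solver failed to meet the residual tolerance")

    h = float(10.0**x if converged else h)
    speciation = {}
    for name, total in totals.items():
        sp = system.species[name]
        if isinstance(sp, StrongIon):
            speciation[name] = np.array([total])
        else:
            speciation[name] = total * sp.fractions(h)
    return h, speciation


def speciation_totals(speciation: dict) -> dict:
    """Recover total concentrations from a speciation map (mass balance check)."""
    return {name: float(np.sum(forms)) for name, forms in speciation.items()}


# -- gas-liquid transfer -----------------------------------------------------


def gas_liquid_rates(gas: GasPartner, s_liq: float, v_gas: float,
                     temperature: float, r_gas: float = R_GAS):
    """Two-film gas-liquid exchange rates.

    R_G->L = K_L a (S_gas - S_liq / K_H) enters the liquid reaction term;
    R_L->G = -R_G->L * V_gas / (R_g T) updates the headspace balance, with
    the headspace volume equal to the computational domain volume.
    """
    r_gl = gas.kla * (gas.s_gas - s_liq / gas.henry)
    r_lg = -r_gl * v_gas / (r_gas * temperature)
    return r_gl, r_lg
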