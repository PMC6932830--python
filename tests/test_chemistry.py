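"""Solute transport, bulk chemostat balance, pH speciation, gas-liquid."""

import numpy as np
import pytest

from biofilmsim.chemistry import (AcidBase, AcidBaseSystem, BulkState,
                                  GasPartner, SoluteSpec, StabilityError,
                                  StrongIon, bulk_update, diffusion_step,
                                  gas_liquid_rates, solve_ph,
                                  solve_to_steady_state, speciation_totals,
                                  stable_dt)
from biofilmsim.domain import BIOFILM, Domain, build_grid


def column_grid(nz, height=1e-4):
    """1-voxel-wide column: periodic sides, substratum below, bulk on top."""
    dx = height / nz
    d = Domain(lengths=(dx, dx, height), periodic=(True, True, False))
    g = build_grid(d, dx)
    g.regions[...] = BIOFILM  # disable bulk clamping inside the column
    return g


class TestDiffusionStep:
    def test_uniform_field_is_fixed_point(self):
        grid = column_grid(16)
        spec = SoluteSpec(name="s", diffusivity=1e-9, s_bulk=2.0)
        S = np.full(grid.shape, 2.0)
        dt = stable_dt(grid, [spec])
        S2, n = diffusion_step(grid, S, spec, 2.0, dt)
        assert np.allclose(S2, 2.0, rtol=1e-14)
        assert n == 0

    def test_stability_bound_enforced(self):
        grid = column_grid(16)
        spec = SoluteSpec(name="s", diffusivity=1e-9)
        S = np.zeros(grid.shape)
        dt_max = grid.voxel_size**2 / (6 * spec.diffusivity)
        with pytest.raises(StabilityError, match="bound"):
            diffusion_step(grid, S, spec, 1.0, 2 * dt_max)

    def test_advective_cfl_enforced(self):
        grid = column_grid(16)
        spec = SoluteSpec(name="s", diffusivity=1e-9)
        S = np.zeros(grid.shape)
        dt = stable_dt(grid, [spec])
        v = np.zeros(grid.shape + (3,))
        v[..., 0] = 10 * grid.voxel_size / dt
        with pytest.raises(StabilityError, match="CFL"):
            diffusion_step(grid, S, spec, 1.0, dt, velocity=v)

    def test_mass_conserved_with_closed_boundaries(self, rng):
        # zero-flux top and bottom, periodic sides, no reaction/advection:
        # the FTCS update conserves total mass to machine precision
        grid = column_grid(16)
        spec = SoluteSpec(name="s", diffusivity=1e-9, bc_top="neumann")
        S = rng.uniform(0.5, 2.0, grid.shape)
        dt = stable_dt(grid, [spec])
        total0 = S.sum()
        for _ in range(25):
            S, _ = diffusion_step(grid, S, spec, 0.0, dt, clamp_bulk=False)
        assert S.sum() == pytest.approx(total0, rel=1e-13)

    def test_bulk_voxels_clamped(self):
        grid = column_grid(8)
        grid.regions[..., -2:] = 2  # BULK
        spec = SoluteSpec(name="s", diffusivity=1e-9, s_bulk=1.0)
        S = np.zeros(grid.shape)
        dt = stable_dt(grid, [spec])
        S, _ = diffusion_step(grid, S, spec, 1.0, dt)
        assert np.all(S[..., -2:] == 1.0)

    def test_advection_transports_downstream(self):
        # uniform velocity along periodic x moves a concentration bump
        d = Domain(lengths=(1.6e-4, 1e-5, 1e-5), periodic=(True, True, False))
        grid = build_grid(d, 1e-5)
        grid.regions[...] = BIOFILM
        spec = SoluteSpec(name="s", diffusivity=1e-9, bc_top="neumann")
        S = np.zeros(grid.shape)
        S[3, 0, 0] = 1.0
        v = np.zeros(grid.shape + (3,))
        v[..., 0] = 1e-4  # m/s
        dt = stable_dt(grid, [spec])
        com0 = (np.arange(grid.shape[0]) * S[:, 0, 0]).sum() / S[:, 0, 0].sum()
        for _ in range(200):
            S, _ = diffusion_step(grid, S, spec, 0.0, dt, velocity=v)
        com1 = (np.arange(grid.shape[0]) * S[:, 0, 0]).sum() / S[:, 0, 0].sum()
        assert com1 > com0 + 0.5


class TestSteadyState:
    def test_no_reaction_converges_to_bulk_value(self):
        grid = column_grid(16)
        spec = SoluteSpec(name="s", diffusivity=1e-9, s_bulk=3.0)
        fields = {"s": np.zeros(grid.shape)}
        iters = solve_to_steady_state(grid, fields, {"s": spec}, {"s": 3.0},
                                      tol=1e-9)
        assert np.allclose(fields["s"], 3.0, rtol=1e-3)
        assert iters > 0

    def test_first_order_sink_matches_cosh_profile(self):
        """Steady 1D reaction-diffusion against the closed form
        S(z) = S_b cosh(z/lambda) / cosh(H/lambda)."""
        H, D, Sb = 1e-4, 1e-9, 1.0
        lam = H / 4
        k = D / lam**2
        grid = column_grid(32, height=H)
        spec = SoluteSpec(name="s", diffusivity=D, s_bulk=Sb)
        fields = {"s": np.full(grid.shape, Sb)}
        solve_to_steady_state(grid, fields, {"s": spec}, {"s": Sb},
                              R_callback=lambda f: {"s": -k * f["s"]},
                              tol=1e-8, max_iters=500_000)
        z = grid.centers(2)
        exact = Sb * np.cosh(z / lam) / np.cosh(H / lam)
        rel = np.abs(fields["s"][0, 0, :] - exact) / exact
        assert rel.max() < 0.01

    def test_constant_source_parabolic_profile(self):
        """Uniform source, zero-flux bottom, Dirichlet top: the steady state
        is S(z) = S_b + (r0 / 2D) (H^2 - z^2)."""
        H, D, Sb, r0 = 1e-4, 1e-9, 1.0, 100.0
        grid = column_grid(32, height=H)
        spec = SoluteSpec(name="s", diffusivity=D, s_bulk=Sb)
        fields = {"s": np.full(grid.shape, Sb)}
        solve_to_steady_state(grid, fields, {"s": spec}, {"s": Sb},
                              R_callback=lambda f: {"s": np.full(grid.shape, r0)},
                              tol=1e-9, max_iters=500_000)
        z = grid.centers(2)
        exact = Sb + r0 / (2 * D) * (H**2 - z**2)
        rel = np.abs(fields["s"][0, 0, :] - exact) / exact
        assert rel.max() < 0.01

    def test_initial_condition_independence(self):
        grid = column_grid(16)
        spec = SoluteSpec(name="s", diffusivity=1e-9, s_bulk=1.0)
        k = 1e-9 / (2.5e-5) ** 2
        cb = lambda f: {"s": -k * f["s"]}
        tol = 1e-9
        from_zero = {"s": np.zeros(grid.shape)}
        from_bulk = {"s": np.full(grid.shape, 1.0)}
        solve_to_steady_state(grid, from_zero, {"s": spec}, {"s": 1.0}, cb, tol=tol)
        solve_to_steady_state(grid, from_bulk, {"s": spec}, {"s": 1.0}, cb, tol=tol)
        assert np.allclose(from_zero["s"], from_bulk["s"], atol=1e-5)

    def test_nonconvergence_raises(self):
        grid = column_grid(8)
        spec = SoluteSpec(name="s", diffusivity=1e-9, s_bulk=1.0)
        fields = {"s": np.zeros(grid.shape)}
        with pytest.raises(RuntimeError, match="converge"):
            solve_to_steady_state(grid, fields, {"s": spec}, {"s": 1.0},
                                  tol=1e-14, max_iters=5)


class TestBulkBalance:
    def test_washin_matches_closed_form(self):
        """With R = 0 the chemostat ODE has S_b(t) = S_in (1 - e^{-Qt/V})."""
        grid = column_grid(4)
        spec = SoluteSpec(name="s", diffusivity=1e-9, s_in=2.0)
        Q, V = 1e-13, 1e-9
        dt = 50.0
        bulk = BulkState(flow_rate=Q, volume=V, biofilm_area=0.0,
                         s_bulk={"s": 0.0})
        t, n = 0.0, 400
        for _ in range(n):
            bulk_update(bulk, {"s": spec}, {}, grid, dt)
            t += dt
        exact = 2.0 * (1 - np.exp(-Q * t / V))
        # forward Euler: O(dt) accuracy
        assert bulk.s_bulk["s"] == pytest.approx(exact, rel=Q / V * dt * 2)

    def test_closed_reactor_constant(self):
        grid = column_grid(4)
        spec = SoluteSpec(name="s", diffusivity=1e-9, s_in=5.0)
        bulk = BulkState(flow_rate=0.0, volume=1e-9, biofilm_area=0.0,
                         s_bulk={"s": 1.5})
        bulk_update(bulk, {"s": spec}, {}, grid, 100.0)
        assert bulk.s_bulk["s"] == 1.5

    def test_consumption_lowers_steady_state_below_influent(self):
        grid = column_grid(4)
        spec = SoluteSpec(name="s", diffusivity=1e-9, s_in=2.0)
        R = {"s": np.full(grid.shape, -1e-3)}
        bulk = BulkState(flow_rate=1e-13, volume=1e-9, biofilm_area=1e-8,
                         s_bulk={"s": 2.0})
        for _ in range(2000):
            bulk_update(bulk, {"s": spec}, R, grid, 100.0)
        assert 0.0 <= bulk.s_bulk["s"] < 2.0

    def test_fixed_bulk_skipped(self):
        grid = column_grid(4)
        spec = SoluteSpec(name="o2", diffusivity=1e-9, s_in=0.0, s_bulk=0.009,
                          fixed_bulk=True)
        bulk = BulkState(flow_rate=1e-10, volume=1e-9, biofilm_area=0.0,
                         s_bulk={"o2": 0.009})
        bulk_update(bulk, {"o2": spec}, {}, grid, 1e4)
        assert bulk.s_bulk["o2"] == 0.009


class TestPH:
    def test_pure_water_is_neutral(self):
        h, _ = solve_ph({}, AcidBaseSystem())
        assert -np.log10(h) == pytest.approx(7.0, abs=1e-9)

    def test_strong_acid_quadratic_closed_form(self):
        c = 1e-3
        system = AcidBaseSystem(species={"cl": StrongIon("cl", charge=-1)})
        h, _ = solve_ph({"cl": c}, system)
        exact = (c + np.sqrt(c**2 + 4e-14)) / 2
        assert h == pytest.approx(exact, rel=1e-9)
        assert -np.log10(h) == pytest.approx(3.0, abs=1e-3)

    def test_strong_base_mirror(self):
        system = AcidBaseSystem(species={"na": StrongIon("na", charge=+1)})
        h, _ = solve_ph({"na": 1e-3}, system)
        assert -np.log10(h) == pytest.approx(11.0, abs=1e-3)

    def test_residual_below_tolerance(self):
        from biofilmsim.chemistry import _charge_imbalance
        system = AcidBaseSystem(species={
            "ac": AcidBase("ac", ka=(1.8e-5,), charge0=0),
            "na": StrongIon("na", charge=+1)})
        totals = {"ac": 5e-3, "na": 1e-3}
        h, _ = solve_ph(totals, system)
        assert abs(_charge_imbalance(h, totals, system)) < 1e-12 * max(1.0, 6e-3)

    def test_half_neutralised_weak_acid_cubic_oracle(self):
        # exact root of the charge-balance cubic for acetate + sodium:
        # h^3 + (ka + C_na) h^2 + (C_na ka - Kw - C_ac ka) h - Kw ka = 0
        ka, kw = 1.8e-5, 1e-14
        c_ac, c_na = 2e-3, 1e-3
        roots = np.roots([1.0, ka + c_na, c_na * ka - kw - c_ac * ka, -kw * ka])
        exact = float(max(r.real for r in roots if abs(r.imag) < 1e-20 and r.real > 0))
        system = AcidBaseSystem(species={
            "ac": AcidBase("ac", ka=(ka,), charge0=0),
            "na": StrongIon("na", charge=+1)})
        h, _ = solve_ph({"ac": c_ac, "na": c_na}, system)
        assert h == pytest.approx(exact, rel=1e-8)
        # ... which lands near pH = pKa, the buffer midpoint
        assert -np.log10(h) == pytest.approx(-np.log10(ka), abs=0.05)

    def test_speciation_mass_balance(self):
        system = AcidBaseSystem(species={
            "co3": AcidBase("co3", ka=(4.3e-7, 4.8e-11), charge0=0),
            "nh4": AcidBase("nh4", ka=(5.6e-10,), charge0=+1)})
        totals = {"co3": 2e-3, "nh4": 1e-3}
        _, speciation = solve_ph(totals, system)
        back = speciation_totals(speciation)
        for name in totals:
            assert back[name] == pytest.approx(totals[name], rel=1e-10)

    def test_adding_acid_never_raises_ph(self):
        system = AcidBaseSystem(species={"cl": StrongIon("cl", charge=-1)})
        hs = [solve_ph({"cl": c}, system)[0]
              for c in np.logspace(-6, -2, 12)]
        assert np.all(np.diff(hs) > 0)  # more acid, more protons

    def test_impossible_balance_reported(self):
        # a pure strong-cation input has no root in the bracket
        system = AcidBaseSystem(species={"na": StrongIon("na", charge=+1)})
        with pytest.raises(ArithmeticError, match="no root"):
            solve_ph({"na": 2.0}, system)


class TestGasLiquid:
    def test_henry_equilibrium_is_zero_flux(self):
        gas = GasPartner(kla=1e-3, henry=2.0, s_gas=1.0)
        r_gl, r_lg = gas_liquid_rates(gas, s_liq=2.0, v_gas=1e-12, temperature=298.15)
        assert r_gl == pytest.approx(0.0, abs=1e-18)
        assert r_lg == pytest.approx(0.0, abs=1e-18)

    def test_direct_evaluation(self):
        gas = GasPartner(kla=1e-3, henry=2.0, s_gas=1.0)
        r_gl, _ = gas_liquid_rates(gas, s_liq=0.0, v_gas=1e-12, temperature=298.15)
        assert r_gl == pytest.approx(1e-3)

    def test_rates_always_opposite_in_sign(self, rng):
        for _ in range(20):
            gas = GasPartner(kla=10 ** rng.uniform(-4, -2),
                             henry=10 ** rng.uniform(-1, 1),
                             s_gas=rng.uniform(0, 2))
            r_gl, r_lg = gas_liquid_rates(gas, rng.uniform(0, 2), 1e-12, 298.15)
            assert r_gl * r_lg <= 0
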