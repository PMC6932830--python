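"""DEM mechanics: neighbour lists, pair forces, Verlet, pressure, relaxation."""

import numpy as np
import pytest

from biofilmsim.agents import Population, mass_from_diameter
from biofilmsim.domain import Domain
from biofilmsim.mechanics import (ForceParams, average_pressure,
                                  build_neighbor_list, compute_forces,
                                  contact_force, drag_force,
                                  eps_adhesion_force, pair_forces, relax,
                                  verlet_step)

from conftest import add_cell


def brute_force_pairs(pop, domain, r):
    """O(N^2) oracle for the pair set within distance r (minimum image)."""
    out = set()
    n = len(pop)
    for i in range(n):
        for j in range(i + 1, n):
            dx = domain.min_image(pop.position[i] - pop.position[j])
            if np.linalg.norm(dx) < r:
                out.add((i, j))
    return out


def random_population(groups, domain, n, rng, diameter=(0.8e-6, 1.4e-6)):
    pop = Population(groups)
    lo, hi = diameter
    for _ in range(n):
        d = rng.uniform(lo, hi)
        pos = np.array([rng.uniform(0, domain.lengths[0]),
                        rng.uniform(0, domain.lengths[1]),
                        rng.uniform(d, domain.lengths[2] - d)])
        pop.add("CELL", pos, mass_from_diameter(d, groups[0].density))
    return pop


class TestNeighborList:
    def test_far_apart_pair_has_empty_list(self, groups, domain):
        pop = Population(groups)
        add_cell(pop, (1e-5, 1e-5, 1e-5))
        add_cell(pop, (5e-5, 5e-5, 5e-5))
        nl = build_neighbor_list(pop, domain, cutoff=3e-6, skin=1e-6)
        assert nl.pairs.size == 0

    def test_matches_brute_force_on_random_cloud(self, groups, domain, rng):
        pop = random_population(groups, domain, 200, rng)
        cutoff, skin = 4e-6, 1e-6
        nl = build_neighbor_list(pop, domain, cutoff, skin)
        got = {tuple(p) for p in nl.pairs}
        expected = brute_force_pairs(pop, domain, cutoff + skin)
        assert got == expected

    def test_periodic_minimum_image_pairing(self, groups, domain):
        pop = Population(groups)
        add_cell(pop, (1e-7, 5e-5, 5e-5))
        add_cell(pop, (1e-4 - 1e-7, 5e-5, 5e-5))  # wrapped neighbour across x
        nl = build_neighbor_list(pop, domain, cutoff=1e-6, skin=0.0)
        assert {tuple(p) for p in nl.pairs} == {(0, 1)}

    def test_rebuild_trigger_on_displacement(self, groups, domain):
        pop = Population(groups)
        add_cell(pop, (1e-5, 1e-5, 1e-5))
        add_cell(pop, (2e-5, 1e-5, 1e-5))
        nl = build_neighbor_list(pop, domain, cutoff=3e-6, skin=1e-6)
        assert not nl.needs_rebuild(pop.position, domain)
        pop.position[0, 0] += 0.6e-6  # > skin/2
        assert nl.needs_rebuild(pop.position, domain)


class TestContactForce:
    def test_touching_spheres_zero_force(self):
        p = ForceParams(kn=1e-3)
        F = contact_force(0.5e-6, 0.5e-6, (0, 0, 0), (1e-6, 0, 0),
                          (0, 0, 0), (0, 0, 0), 1e-16, 1e-16, p)
        assert np.allclose(F, 0)

    def test_overlap_magnitude_direct_evaluation(self):
        # r = 0.5 um each, centres 0.9 um apart: delta = 0.1 um
        p = ForceParams(kn=1e-3, gamma_n=0.0)
        F = contact_force(0.5e-6, 0.5e-6, (0, 0, 0), (0.9e-6, 0, 0),
                          (0, 0, 0), (0, 0, 0), 1e-16, 1e-16, p)
        assert np.linalg.norm(F) == pytest.approx(1e-3 * 1e-7, rel=1e-12)
        assert F[0] < 0  # repulsive: pushes i away from j

    def test_newtons_third_law_on_random_pairs(self, groups, domain, rng):
        pop = random_population(groups, domain, 60, rng)
        # compress everything into a small ball to force many overlaps
        pop.position = 2e-5 + (pop.position - 5e-5) * 0.05
        params = ForceParams(kn=1e-4, gamma_n=1e5, hamaker=1e-20)
        pop.velocity = rng.normal(scale=1e-6, size=pop.velocity.shape)
        nl = build_neighbor_list(pop, domain, cutoff=5e-6, skin=1e-6)
        F, _ = pair_forces(pop, domain, params, nl)
        assert np.allclose(F.sum(axis=0), 0.0, atol=1e-18)

    def test_neighbor_evaluation_equals_all_pairs(self, groups, domain, rng):
        """Cell-list force sum must equal the brute-force all-pairs sum."""
        pop = random_population(groups, domain, 200, rng)
        pop.position[:, :2] *= 0.3  # densify laterally to create contacts
        params = ForceParams(kn=1e-4, gamma_n=1e4, hamaker=1e-20)
        nl = build_neighbor_list(pop, domain, cutoff=5e-6, skin=1e-6)
        F_fast, vir_fast = pair_forces(pop, domain, params, nl)
        all_pairs = np.array(sorted((i, j) for i in range(len(pop))
                                    for j in range(i + 1, len(pop))))
        from biofilmsim.mechanics import NeighborList
        nl_all = NeighborList(pairs=all_pairs, cutoff=np.inf, skin=0.0,
                              ref_positions=pop.position.copy())
        F_all, vir_all = pair_forces(pop, domain, params, nl_all)
        assert np.allclose(F_fast, F_all, rtol=1e-12, atol=1e-25)
        assert vir_fast == pytest.approx(vir_all, rel=1e-12)


class TestAdhesion:
    def test_outside_cutoff_zero(self):
        p = ForceParams(hamaker=1e-20)
        F = eps_adhesion_force(1e-6, 1e-6, (0, 0, 0), (4e-6, 0, 0), p)
        assert np.allclose(F, 0)

    def test_direct_evaluation_of_vdw_magnitude(self):
        # R = 1 um both, separation h = 10 nm, Ha = 1e-20 J:
        # r_eff = 0.5 um, |F| = Ha r_eff / (12 h^2)
        p = ForceParams(hamaker=1e-20, h_floor=1e-9)
        F = eps_adhesion_force(1e-6, 1e-6, (0, 0, 0), (2.01e-6, 0, 0), p)
        expected = 1e-20 * 0.5e-6 / (12 * (1e-8) ** 2)
        assert np.linalg.norm(F) == pytest.approx(expected, rel=1e-9)
        assert F[0] > 0  # attractive: pulls i toward j

    def test_two_body_attraction_reduces_separation(self, groups, domain):
        pop = Population(groups)
        add_cell(pop, (4.0e-5, 5e-5, 5e-5))
        add_cell(pop, (4.12e-5, 5e-5, 5e-5))  # gap 0.2 um, inside adhesion cutoff
        params = ForceParams(kn=1e-4, gamma_n=1e6, hamaker=1e-22)
        d0 = np.linalg.norm(pop.position[1] - pop.position[0])
        # window > max_steps: integrate the full trajectory, no early exit
        relax(pop, domain, params, dt=1e-7, max_steps=3000, window=4000)
        d1 = np.linalg.norm(pop.position[1] - pop.position[0])
        assert d1 < d0
        # and never closer than the contact equilibrium allows
        assert d1 > 0.9 * float(pop.radius.sum())


class TestDrag:
    def test_no_slip_no_drag(self, groups, grid, domain):
        pop = Population(groups)
        add_cell(pop, (5e-6, 5e-6, 5e-6), velocity=(1e-5, 0, 0))
        v = np.zeros(grid.shape + (3,))
        v[..., 0] = 1e-5
        F = drag_force(pop, grid, v, ForceParams())
        assert np.allclose(F, 0)

    def test_sign_follows_the_flow(self, groups, grid):
        pop = Population(groups)
        add_cell(pop, (5e-6, 5e-6, 5e-6))
        v = np.zeros(grid.shape + (3,))
        v[..., 0] = 1e-4
        F = drag_force(pop, grid, v, ForceParams())
        assert F[0, 0] > 0 and abs(F[0, 1]) < 1e-30

    def test_linear_in_slip_velocity(self, groups, grid):
        pop = Population(groups)
        add_cell(pop, (5e-6, 5e-6, 5e-6))
        v1 = np.zeros(grid.shape + (3,))
        v1[..., 0] = 1e-4
        F1 = drag_force(pop, grid, v1, ForceParams())
        F2 = drag_force(pop, grid, 3 * v1, ForceParams())
        assert np.allclose(F2, 3 * F1, rtol=1e-12)


class TestVerletAndPressure:
    def test_no_force_no_motion(self, groups, domain):
        pop = Population(groups)
        add_cell(pop, (5e-5, 5e-5, 5e-5))
        nl = build_neighbor_list(pop, domain, cutoff=3e-6, skin=1e-6)
        x0 = pop.position.copy()
        for _ in range(10):
            verlet_step(pop, domain, ForceParams(), nl, 1e-7)
        assert np.array_equal(pop.position, x0)

    def test_constant_force_kinematics(self, groups, domain):
        """x(t) = F t^2 / 2m under a constant external force."""
        pop = Population(groups)
        i = add_cell(pop, (5e-5, 5e-5, 5e-5))
        m = pop.mass[i]
        Fext = np.array([2e-15, 0, 0])
        dt, n = 1e-7, 500
        x = pop.position[i, 0]
        v = 0.0
        for _ in range(n):
            # velocity Verlet with a constant force, done by hand on pop arrays
            pop.force[i] = Fext
            pop.velocity[i] += 0.5 * dt * Fext / m
            pop.position[i] += dt * pop.velocity[i]
            pop.velocity[i] += 0.5 * dt * Fext / m
        t = n * dt
        exact = x + 0.5 * Fext[0] / m * t**2
        assert pop.position[i, 0] == pytest.approx(exact, rel=1e-9)

    def test_momentum_conserved_in_two_body_contact(self, groups, domain):
        pop = Population(groups)
        add_cell(pop, (5.00e-5, 5e-5, 5e-5))
        add_cell(pop, (5.09e-5, 5e-5, 5e-5))  # overlapping cores
        params = ForceParams(kn=1e-4, gamma_n=1e5, hamaker=0.0)
        nl = build_neighbor_list(pop, domain, cutoff=3e-6, skin=1e-6)
        F, _ = compute_forces(pop, domain, params, nl)
        pop.force = F
        for _ in range(200):
            verlet_step(pop, domain, params, nl, 1e-7)
        p_total = (pop.mass[:, None] * pop.velocity).sum(axis=0)
        assert np.allclose(p_total, 0.0, atol=1e-26)

    def test_single_stationary_particle_zero_pressure(self, groups):
        pop = Population(groups)
        add_cell(pop, (5e-5, 5e-5, 5e-5))
        assert average_pressure(pop, 0.0) == 0.0

    def test_kinetic_pressure_closed_form(self, groups):
        pop = Population(groups)
        i = add_cell(pop, (5e-5, 5e-5, 5e-5), velocity=(1e-5, 0, 0))
        m = pop.mass[i]
        V = m / pop.density[i]
        assert average_pressure(pop, 0.0) == pytest.approx(m * 1e-10 / (3 * V))

    def test_static_overlap_virial_positive(self, groups, domain):
        pop = Population(groups)
        add_cell(pop, (5.00e-5, 5e-5, 5e-5))
        add_cell(pop, (5.09e-5, 5e-5, 5e-5))
        params = ForceParams(kn=1e-4, gamma_n=0.0)
        nl = build_neighbor_list(pop, domain, cutoff=3e-6, skin=1e-6)
        _, virial = pair_forces(pop, domain, params, nl)
        assert virial > 0
        assert average_pressure(pop, virial) > 0

    def test_empty_system_pressure_error(self, groups):
        with pytest.raises(ValueError):
            average_pressure(Population(groups), 0.0)

    def test_damped_head_on_collision_dissipates_energy(self, groups, domain):
        # two spheres collide head-on; with gamma_n > 0 the rebound is slower
        pop = Population(groups)
        add_cell(pop, (4.8e-5, 5e-5, 5e-5), velocity=(+2e-3, 0, 0))
        add_cell(pop, (5.2e-5, 5e-5, 5e-5), velocity=(-2e-3, 0, 0))
        params = ForceParams(kn=1e-4, gamma_n=1e7, hamaker=0.0)
        nl = build_neighbor_list(pop, domain, cutoff=5e-6, skin=1e-6)
        F, _ = compute_forces(pop, domain, params, nl)
        pop.force = F
        ke0 = float(np.einsum("i,ij,ij->", pop.mass, pop.velocity, pop.velocity))
        for _ in range(20_000):  # through the collision
            verlet_step(pop, domain, params, nl, 1e-7)
        d = np.linalg.norm(pop.position[1] - pop.position[0])
        assert d >= 0.99 * pop.radius.sum()  # rebound complete (or creeping apart)
        ke1 = float(np.einsum("i,ij,ij->", pop.mass, pop.velocity, pop.velocity))
        assert ke1 < 0.5 * ke0


class TestRelaxation:
    def test_exits_immediately_when_at_rest(self, groups, domain):
        pop = Population(groups)
        add_cell(pop, (2e-5, 5e-5, 5e-5))
        add_cell(pop, (8e-5, 5e-5, 5e-5))
        steps, P = relax(pop, domain, ForceParams(hamaker=0.0), dt=1e-7)
        assert steps == 0
        assert P == 0.0

    def test_two_overlapping_spheres_separate(self, groups, domain):
        pop = Population(groups)
        add_cell(pop, (5.00e-5, 5e-5, 5e-5))
        add_cell(pop, (5.095e-5, 5e-5, 5e-5))  # 5% overlap
        params = ForceParams(kn=1e-4, gamma_n=1e6, hamaker=0.0)
        relax(pop, domain, params, dt=1e-7, max_steps=20_000, window=100)
        d = np.linalg.norm(pop.position[1] - pop.position[0])
        rsum = pop.radius.sum()
        assert d >= rsum * (1 - 1e-3)

    def test_relaxation_reduces_max_overlap(self, groups, domain, rng):
        pop = random_population(groups, domain, 40, rng)
        pop.position = 3e-5 + (pop.position - 5e-5) * 0.08  # force overlaps
        pop.position[:, 2] = np.maximum(pop.position[:, 2], pop.radius)

        def max_overlap(pop):
            worst = 0.0
            for i in range(len(pop)):
                for j in range(i + 1, len(pop)):
                    dx = domain.min_image(pop.position[i] - pop.position[j])
                    ov = pop.radius[i] + pop.radius[j] - np.linalg.norm(dx)
                    worst = max(worst, ov)
            return worst

        ov0 = max_overlap(pop)
        assert ov0 > 0
        params = ForceParams(kn=1e-4, gamma_n=1e6)
        relax(pop, domain, params, dt=1e-7, max_steps=10_000, window=100)
        assert max_overlap(pop) <= ov0
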