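# Methods

This note documents the model, its numerical treatment, the choices made
where the design was genuinely open, and what the synthetic scenarios do
and do not demonstrate.

## Model structure and coupling

The simulator couples three sub-models that live on separate timescales:
mechanics (≈10⁻⁷–10⁻⁸ s), solute transport (≈10⁻⁴–10⁻¹ s per explicit
sweep), and biology (minutes to hours). Within one biological step, in
order: the solute fields are iterated to a pseudo steady state against the
*frozen* biomass distribution; the bulk chemostat is advanced with the
converged reaction field; every agent grows against the frozen solute
field; instantaneous events fire (division, death/removal, EPS
excretion); the community is mechanically relaxed; regions and
bookkeeping are updated. Each stage is an independently switchable
process ("fix"), and disabling one never perturbs the others. All
randomness flows through a single seeded PCG64 generator, which makes
trajectories bit-reproducible and restartable (the restart file stores
the generator state).

## Domain, grid and regions

The domain is a rectangular box with cubic voxels (single Δx; the
divisibility of each edge is enforced to 1e-9 relative). Coordinates are
0-based with half-open voxels; units are SI throughout and concentrations
kg m⁻³. The box is layered into biofilm / boundary-layer / bulk regions:
the biofilm top is the maximum of (z + outer radius) over agents — the
EPS shell counts, since the biofilm volume is the volume occupied by
agents *and* their EPS — and both interfaces snap up to whole voxel
boundaries so regions conform to the grid. The boundary-layer height
above the film is a user parameter (20 µm in the shipped scenario). Bulk
voxels are clamped to the chemostat concentration every transport sweep
(perfect mixing).

## Biology

Growth integrates dm/dt = μm with forward Euler per biological step.
Division triggers at a threshold *core* diameter (biomass, not the EPS
shell, drives division) with ≥; the daughter fraction is Uniform(0.4,
0.6), the EPS shell splits with the same fraction, and the second
daughter is placed at centre distance r₁ + r₂ along a uniform random
direction (touching spheres; a `division_distance: diameter_sum` switch
reproduces the alternative reading of daughter placement). A placement
below the substratum is reflected about z = r rather than resampled, so
the random draw count per division is fixed. Death uses strict < on the
core diameter; DEAD agents keep their mechanics (they occupy space) but
their only activity is first-order lysis back to organic substrate,
implemented through the group's decay stoichiometry so released mass
exactly matches the mass decrement. Removal happens below one tenth of
the death diameter. HET-like groups accumulate shell mass at the EPS
share Y_EPS/Y of positive growth and excrete a Uniform(0.4, 0.6) fraction
of the shell as a free EPS particle (density 30 kg m⁻³, well below the
cell's 150 kg m⁻³) once outer/core diameter exceeds the shell-ratio
threshold (1.25 in the shipped scenario).

## Kinetics

The Monod model is parameter-agnostic: functional groups declare
pathways, each with Monod terms, optional inhibition terms (used for
oxygen inhibition of denitrification), an anoxic reduction factor η, and
a stoichiometry in kg solute per kg new biomass. Zero concentrations are
handled natively (a Monod factor of 0), with no concentration floor. The
voxel reaction field is assembled from per-voxel biomass totals per
group, which is algebraically identical to the per-agent sum because
kinetic parameters are shared within a group; the literal per-agent sum
is retained as a cross-check (`accumulate_voxel_reactions`) and the two
are asserted equal in the tests.

The energy model computes μ = Y (q_met − m_req) with q_met saturating
Monod-style on the *active* (non-charged) substrate forms, and solute
turnover R = μ (Cat/Y + Ana) X. Cat and Ana are config-supplied free
energies (already temperature-adjusted); yields come precomputed from the
energy-dissipation method. The neutral-form fractions are obtained from
the per-voxel charge balance once per biological step and frozen through
the transport sweep: the charge balance is quasi-instantaneous relative
to transport, and its drift within one step is second order — solving it
every FTCS sweep would multiply the cost of a step by orders of magnitude
for no visible change in the fields.

## Transport and chemistry numerics

FTCS: forward Euler in time, 7-point Laplacian and central-difference
advection on voxel centres. The timestep defaults to 0.9× the 3D
stability bound Δx²/6D, and both that bound and the advective CFL are
enforced with errors that report the admissible step. Boundary
conditions: Dirichlet at the bulk value on the top face (ghost value
2S_b − S), zero-flux at the substratum, periodic on periodic side faces
and zero-flux on fixed ones. Central-difference advection is kept for
fidelity to the discretisation choice; high-Péclet fields need finer
grids (no upwinding). Steady state is declared when the maximum relative
per-sweep change falls below a tolerance (default 1e-6; the oracle tests
use 1e-8–1e-9). Negative concentrations after a sweep are floored at
zero and counted.

The pH solver works in mol L⁻¹ (molar masses convert from transport
units), supports strong ions and polyprotic acid-base systems with
closed-form speciation fractions, and brackets the root in
[1e-14, 1] mol L⁻¹: Newton–Raphson on log₁₀[H⁺] with a Brent fallback;
the charge-balance residual is driven below 1e-12 × max(1, total ionic
concentration). Gas–liquid exchange follows two-film kinetics
R_G→L = K_L a (S_gas − S_liq/K_H), with the liquid-side term entering the
reaction field per sweep and the headspace balance
R_L→G = −R_G→L V_gas/(R_g T) advanced once per biological step from the
domain-mean liquid concentration; the headspace volume equals the domain
volume.

## Mechanics

Pair interactions act between neighbour-list pairs built with a
cell-binned kd-tree under periodic minimum image (non-periodic axes are
padded so no spurious image falls inside the cutoff); the list rebuilds
when any particle has moved more than half the skin. Contact is Hookean
with viscoelastic damping on the *core* radii; adhesion is a van der
Waals attraction on the *outer* radii between shell-bearing groups
(HET–HET, HET–EPS, EPS–EPS), with the separation floored at h_floor
(default 1 nm) to regularise the 1/h² singularity and a cutoff of 1.5×
the outer-radius sum. Drag uses the volume-fraction-weighted form with a
Stokes-type correction β = 18 μ_f ε_f / d_p² by default. Rotation is not
modelled (no torque model is defined for these forces).

Relaxation integrates velocity Verlet until the virial pressure's
relative spread over a sliding window (default 100 steps) falls below
1e-3; a system at rest with zero forces exits immediately. Between
biological steps the driver relaxes *quasi-statically*: velocities are
zeroed at relaxation start and the per-step displacement is capped at
0.1× the smallest core radius (limited-distance NVE integration). The cap
matters in practice: a freshly excreted EPS particle that lands
overlapping a crowded neighbour would otherwise be ejected ballistically
by the stiff contact spring. Direct calls to `verlet_step`/`relax` leave
both switches off, preserving the plain Newtonian contract (momentum
conservation, energy dissipation) that the tests exercise.

Parameter balance: with K_n = 1e-4 N m⁻¹, a Hamaker coefficient of
1e-22 J and the 1 nm floor give an adhesive equilibrium overlap of ~2% of
a radius; substantially larger H_a overwhelms the spring at the floor and
produces unphysical interpenetration. The shipped scenario uses
dt_mech = 5e-8 s, safely inside the contact oscillation period of the
lightest (EPS) particles.

## Observables

The biofilm surface is a height map over (x, y) bins (default bin = voxel
size): the top of the highest outer sphere per bin, consistent with the
biofilm-thickness definition. Roughness is the population standard
deviation of bin heights (the discrete form of the area integral);
area density counts core *and* shell mass per substratum area. The floc
equivalent diameter is that of the volume-equivalent sphere; the fractal
dimension is a box-counting slope over dyadic scales (≥4), undefined (and
reported absent) for a single particle. A compact lattice block measures
3.0; small sparse colonies measure lower, as box counting should.

## The shipped nitrifying scenario

`make_scenario("nitrifying_community")` is a desk-scale analogue of a
multi-group nitrifying reactor biofilm: 40 cells (16 HET, 12 AOB,
12 NOB) on the substratum of a 100×100×100 µm box with 10 µm voxels,
aerated oxygen (bulk held at 0.01 kg m⁻³), ammonium-rich influent
(0.1 kg m⁻³), no nitrite/nitrate inflow, and a 15-minute biological step.
Kinetic and stoichiometric constants are standard activated-sludge-style
values (μ_max: HET 6 d⁻¹, AOB ≈1.2 d⁻¹, NOB ≈0.86 d⁻¹; yields 0.61,
0.33, 0.083; ASM-type oxygen/nitrogen stoichiometry). The chemostat
constants (V = 2e-12 m³, Q = 2e-16 m³ s⁻¹, influent substrate 1.5e-3 vs
K_S = 4e-3 kg m⁻³) were chosen so the organic substrate turns limiting
for the heterotrophs within a ~40 h run that a single CPU completes in
about three minutes; with a larger reservoir the same succession occurs,
only later and with far more particles. A 170-step run shows the three
qualitative signatures of substrate-limited nitrifying films: early
heterotroph dominance, a later recovery of the nitrifier biomass share,
and monotone total-biomass growth before steady state.

What the synthetic scenarios do **not** show: real inocula are not
monodisperse spheres, real EPS is not a uniform-density shell, the
prescribed-velocity drag exercises the force law but not fluid feedback
(no computational fluid dynamics is included), and the scenario's
parameter set is representative rather than fitted to any particular
reactor. Passing tests demonstrate the correctness of the mechanisms and
their coupling, not quantitative agreement with a specific experimental
system.

## Known limitations

* Explicit FTCS transport only; stiff (very fine grid / fast reaction)
  problems would benefit from an implicit or multigrid solver.
* Central-difference advection oscillates at high Péclet numbers.
* The energy model's q_met functional form is a Monod saturation on the
  active species; more detailed thermodynamic rate laws would slot into
  `EnergyGroup` without interface changes.
* Single-process execution; the per-voxel independence of the pH solve
  and the additivity of the reaction field are the natural
  parallelisation seams.
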