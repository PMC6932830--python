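import numpy as np
import pytest

from biofilmsim.agents import FunctionalGroup, Pathway, Population, mass_from_diameter
from biofilmsim.domain import Domain, build_grid


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def cell_group():
    """A generic HET-like microbe with EPS shell parameters."""
    return FunctionalGroup(
        name="CELL", density=150.0, division_diameter=1.3e-6,
        death_diameter=6.5e-7, mu_max=6.94e-5, decay_rate=2.3e-6,
        yield_=0.61, eps_yield=0.18, eps_density=30.0,
        shell_ratio_threshold=1.25, adhesive=True,
        pathways=[Pathway(name="aerobic",
                          monod={"substrate": 4e-3, "o2": 2e-4},
                          stoich={"substrate": -1.6393, "o2": -0.6393})],
    )


@pytest.fixture
def groups(cell_group):
    return [
        cell_group,
        FunctionalGroup(name="EPS", density=30.0, biotic=False, adhesive=True),
        FunctionalGroup(name="DEAD", density=150.0, biotic=False,
                        decay_rate=1e-5, decay_stoich={"substrate": 1.0}),
    ]


@pytest.fixture
def population(groups):
    return Population(groups)


@pytest.fixture
def domain():
    return Domain(lengths=(1e-4, 1e-4, 1e-4), periodic=(True, True, False))


@pytest.fixture
def grid(domain):
    return build_grid(domain, 1e-5)


def add_cell(pop, position, diameter=1e-6, group="CELL", outer_mass=0.0,
             velocity=None):
    g = pop.groups[pop.group_index(group)]
    return pop.add(group, position, mass_from_diameter(diameter, g.density),
                   outer_mass=outer_mass, velocity=velocity)
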