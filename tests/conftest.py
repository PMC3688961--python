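import numpy as np
import pytest

from oakmosaic import (
    Landscape,
    Landtype,
    default_landtypes,
    default_species,
)


@pytest.fixture(scope="session")
def species():
    return default_species()


@pytest.fixture(scope="session")
def landtypes():
    return default_landtypes()


@pytest.fixture
def open_landtype():
    """A low-quality landtype with MGSO 1 and certain establishment, handy
    for deterministic single-cell experiments."""
    sep = {n: 1.0 for n in default_species().names}
    return Landtype(9, "ridgetop", 1.0, sep)


def make_single_cell(species_set, landtype, cohorts=()):
    """A 1x1 landscape holding the given (species_name, age, trees/ha) cohorts."""
    land = Landscape(
        species_set, (1, 1), np.array([landtype.id]), np.zeros(1, int),
        np.zeros(1, int), {landtype.id: landtype},
    )
    for name, age, dens in cohorts:
        land.add_cohort(0, name, age, dens)
    return land


@pytest.fixture
def single_cell_factory(species):
    def factory(landtype, cohorts=()):
        return make_single_cell(species, landtype, cohorts)

    return factory
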