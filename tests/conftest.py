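import numpy as np
import pytest

from mortens import AgeGroupScheme, MortalitySurface


@pytest.fixture
def scheme():
    return AgeGroupScheme()


@pytest.fixture
def toy_scheme():
    """Three age groups: 0, 1-4, 5+ (small enough to reason by hand)."""
    return AgeGroupScheme(lower_bounds=(0, 1, 5), a_fractions=(0.1, 0.5, 0.5))


def make_surface(deaths, population, first_year=2000, country="toyland",
                 sex="female", scheme=None, observed=None):
    deaths = np.asarray(deaths, dtype=float)
    scheme = scheme or AgeGroupScheme(
        lower_bounds=tuple(range(0, deaths.shape[0])),
        a_fractions=(0.5,) * deaths.shape[0],
    )
    return MortalitySurface(country=country, sex=sex, first_year=first_year,
                            deaths=deaths, population=population,
                            scheme=scheme, observed=observed)


@pytest.fixture
def toy_surface(toy_scheme):
    deaths = np.array([[10.0, 12.0], [4.0, 5.0], [50.0, 55.0]])
    pop = np.full((3, 2), 1000.0)
    return make_surface(deaths, pop, scheme=toy_scheme)
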