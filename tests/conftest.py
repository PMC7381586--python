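import numpy as np
import pytest

from kinmark import Individual, Population, SimulationConfig, generate_population


@pytest.fixture(scope="session")
def standard_config() -> SimulationConfig:
    """The standard validation scenario: 100 M + 100 F adults, lambda = 2,
    juvenile total fixed at 200, so N = 400."""
    return SimulationConfig(N_M=100, N_F=100, offspring_rate=2.0, N_J=200, n=50, seed=12345)


@pytest.fixture(scope="session")
def standard_population(standard_config) -> Population:
    pop = generate_population(standard_config)
    assert pop.N == 400
    return pop


@pytest.fixture(scope="session")
def tiny_population() -> Population:
    """Hand-built 3 M + 3 F + 4 J pedigree, small enough for exhaustive enumeration."""
    males = [Individual(f"M{i}", "adult", "male") for i in (1, 2, 3)]
    females = [Individual(f"F{i}", "adult", "female") for i in (1, 2, 3)]
    juveniles = [
        Individual("J1", "juvenile", "male", mother_id="F1", father_id="M1"),
        Individual("J2", "juvenile", "female", mother_id="F1", father_id="M2"),
        Individual("J3", "juvenile", "male", mother_id="F2", father_id="M2"),
        Individual("J4", "juvenile", "female", mother_id="F3", father_id="M3"),
    ]
    return Population(tuple(males + females + juveniles))


@pytest.fixture
def hand_subsample() -> list[Individual]:
    """Six sampled individuals: 1 adult male, 1 adult female, 4 juveniles of
    which two have their father in the sample and one its mother."""
    return [
        Individual("M1", "adult", "male"),
        Individual("F1", "adult", "female"),
        Individual("J1", "juvenile", "male", mother_id="F9", father_id="M1"),
        Individual("J2", "juvenile", "female", mother_id="F8", father_id="M1"),
        Individual("J3", "juvenile", "male", mother_id="F1", father_id="M7"),
        Individual("J4", "juvenile", "female", mother_id="F5", father_id="M6"),
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
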