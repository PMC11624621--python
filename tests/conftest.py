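import pytest
from hypothesis import settings

settings.register_profile("derandomized", derandomize=True)
settings.load_profile("derandomized")

from loadtune import (
    Individual,
    Population,
    Variant,
    generate_melody,
    generate_population,
)
from loadtune.synthetic_data import MelodySpec, PopulationSpec


@pytest.fixture(scope="session")
def tiny_population() -> Population:
    """Three individuals, five variants on two scaffolds, hand-checkable."""
    variants = [
        Variant("v1", "scafA", 100, 5.0),
        Variant("v2", "scafA", 200, 7.0),
        Variant("v3", "scafB", 50, 3.0),
        Variant("v4", "scafB", 80, 10.0),
        Variant("v5", "scafB", 120, 2.0),
    ]
    individuals = [
        Individual("X", {"v1": 2, "v2": 1, "v3": 0, "v4": 1, "v5": 0}),
        Individual("Y", {"v1": 1, "v2": 0, "v3": 2, "v4": 1, "v5": 0}),
        Individual("Z", {"v1": 0, "v2": 0, "v3": 0, "v4": 2, "v5": 1}),
    ]
    return Population(variants=variants, individuals=individuals)


@pytest.fixture(scope="session")
def default_population() -> Population:
    """The default six-founder synthetic population (seed 0)."""
    return generate_population(PopulationSpec(seed=0))


@pytest.fixture(scope="session")
def melody():
    """The default 104-onset synthetic melody."""
    return generate_melody(MelodySpec(seed=0))
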