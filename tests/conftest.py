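import numpy as np
import pytest

from radtse import (
    ModelParameters,
    PopulationModel,
    StasisProblem,
    published_population,
)

# silence benign overflow warnings from penalty-region probes in optimizers
np.seterr(over="ignore", invalid="ignore")


@pytest.fixture(scope="session")
def pop() -> PopulationModel:
    """The bundled reference population (three studies, three compounds)."""
    return published_population()


@pytest.fixture(scope="session")
def median3(pop) -> ModelParameters:
    """Median subject of study 3 (smallest long-term coefficient)."""
    return pop.median_parameters(3)


@pytest.fixture(scope="session")
def median1(pop) -> ModelParameters:
    return pop.median_parameters(1)


@pytest.fixture(scope="session")
def problem() -> StasisProblem:
    return StasisProblem()


def random_parameters(rng: np.random.Generator, **overrides) -> ModelParameters:
    """A random but admissible parameter set for property tests."""
    kg = rng.uniform(0.1, 0.8)
    defaults = dict(
        kg=kg,
        kk=rng.uniform(0.0, 0.9) * kg,
        alpha=rng.uniform(0.01, 0.15),
        gamma=rng.uniform(0.005, 0.08),
        v0=rng.uniform(5.0, 120.0),
        a=rng.uniform(0.0, 1.0),
        b=rng.uniform(0.0, 0.5),
    )
    defaults.update(overrides)
    return ModelParameters(**defaults)
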