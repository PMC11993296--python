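import dataclasses

import numpy as np
import pytest

from pltrecon import CohortConfig, PopulationParameters, TreatmentRegimen


@pytest.fixture(scope="session")
def pop() -> PopulationParameters:
    """Published typical values with their %CVs."""
    return PopulationParameters()


@pytest.fixture(scope="session")
def pop_no_iiv(pop) -> PopulationParameters:
    """Typical values with all inter-individual variability switched off."""
    return dataclasses.replace(pop, cv={})


@pytest.fixture(scope="session")
def typical_regimen() -> TreatmentRegimen:
    """Conditioning -6..-2, unrelated donor, no ATG, no transfusions."""
    return TreatmentRegimen()


@pytest.fixture(scope="session")
def atg_regimen() -> TreatmentRegimen:
    """800 mg/day ATG on days -4..-2 on top of the typical regimen."""
    return TreatmentRegimen(atg_doses=((-4.0, 800.0), (-3.0, 800.0), (-2.0, 800.0)))


@pytest.fixture(scope="session")
def config() -> CohortConfig:
    return CohortConfig()


@pytest.fixture(scope="session")
def small_cohort(config, pop):
    """A reusable 12-subject synthetic cohort."""
    from pltrecon import generate_cohort

    return generate_cohort(config, pop, 12, seed=20240901)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
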