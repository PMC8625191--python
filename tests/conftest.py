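import numpy as np
import pytest

from meropopk import PopulationModel
from meropopk.synthetic import StudyDesign, generate_cohort, generate_study


@pytest.fixture(scope="session")
def model() -> PopulationModel:
    """Final population model estimates (packaged defaults)."""
    return PopulationModel()


@pytest.fixture(scope="session")
def study26(model):
    """One seeded 26-subject noisy study dataset."""
    rng = np.random.default_rng(1861)
    design = StudyDesign()
    cohort = generate_cohort(design, rng)
    return generate_study(model, cohort, design, rng)


@pytest.fixture(scope="session")
def study8(model):
    """A small 8-subject dataset for fit-based tests."""
    rng = np.random.default_rng(77)
    design = StudyDesign(n_subjects=8)
    cohort = generate_cohort(design, rng)
    return generate_study(model, cohort, design, rng)


def make_study(model, n_subjects: int, seed: int):
    rng = np.random.default_rng(seed)
    design = StudyDesign(n_subjects=n_subjects)
    cohort = generate_cohort(design, rng)
    return generate_study(model, cohort, design, rng)
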