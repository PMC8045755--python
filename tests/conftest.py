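import numpy as np
import pandas as pd
import pytest

from histomorph.patientfeat import feature_names
from histomorph.synthdata import CohortSpec, TileSpec, generate_cohort, generate_tile


@pytest.fixture(scope="session")
def names() -> list[str]:
    return feature_names()


@pytest.fixture(scope="session")
def tile50():
    """A 512x512 tile with 50 well-separated nuclei plus its ground truth."""
    spec = TileSpec(n_nuclei=50, min_separation=30, seed=7)
    return generate_tile(spec)


@pytest.fixture(scope="session")
def null_cohort():
    """200 patients, no planted shifts or survival signal."""
    cohort, truth = generate_cohort(CohortSpec(n_patients=200, seed=101))
    return cohort


@pytest.fixture(scope="session")
def planted_cohort(names):
    """300 patients with a 3-feature proportional-hazards signal."""
    betas = {names[5]: 0.8, names[40]: -0.8, names[99]: 0.8}
    cohort, truth = generate_cohort(CohortSpec(n_patients=300, cox_betas=betas, seed=202))
    return cohort, betas


def triangle_centroids() -> np.ndarray:
    return np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 4.0]])


@pytest.fixture
def demo_cohort30(names):
    """Small cohort for LOOCV plumbing tests."""
    betas = {names[0]: 1.0, names[20]: -1.0}
    cohort, _ = generate_cohort(CohortSpec(n_patients=30, cox_betas=betas, seed=7))
    return cohort
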