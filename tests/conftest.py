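import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from metaboclock import MetaboliteMatrix
from metaboclock.simulate import SimulationConfig, generate_cohort_pair

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


SMALL_SIM = SimulationConfig(
    n_subjects=(300, 150), n_metabolites=120, n_age_assoc=40,
    n_obstr_assoc=40, n_shared=20, n_discrepant=8, n_severe=4, seed=7,
)


@pytest.fixture(scope="session")
def small_pair():
    """A small simulated cohort pair shared across tests (read-only)."""
    return generate_cohort_pair(SMALL_SIM)


@pytest.fixture
def tiny_matrix():
    """3 samples x 3 metabolites, complete, one batch."""
    data = pd.DataFrame(
        [[2.0, 10.0, 1.0], [4.0, 20.0, 2.0], [6.0, 30.0, 4.0]],
        index=["s1", "s2", "s3"], columns=["m1", "m2", "m3"],
    )
    return MetaboliteMatrix(
        data,
        batch=pd.Series(["b1"] * 3, index=data.index),
        cohort=pd.Series(["A"] * 3, index=data.index),
    )


def make_matrix(values, batch=None, cohort="A", samples=None, mets=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    samples = samples or [f"s{i}" for i in range(n)]
    mets = mets or [f"m{j}" for j in range(m)]
    data = pd.DataFrame(values, index=samples, columns=mets)
    batch = batch if batch is not None else ["b1"] * n
    return MetaboliteMatrix(
        data, batch=pd.Series(batch, index=data.index),
        cohort=pd.Series([cohort] * n, index=data.index),
    )
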