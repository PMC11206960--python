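import numpy as np
import pandas as pd
import pytest

from cacoperm import SyntheticSpec, generate_qspr_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """200-compound synthetic dataset with planted structure."""
    spec = SyntheticSpec(
        n_compounds=200, n_informative=5, n_redundant=5, n_noise=20,
        n_near_constant=2, missing_fraction=0.02, noise_sd=0.4, seed=11,
    )
    matrix, response, truth = generate_qspr_dataset(spec)
    return spec, matrix, response, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_frame(values, columns=None):
    values = np.asarray(values, dtype=float)
    columns = columns or [f"c{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, columns=columns)
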