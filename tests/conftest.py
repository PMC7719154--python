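import warnings

import numpy as np
import pytest

from cbparc.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default bilateral 8-subject cohort with 4 planted parcels."""
    return generate_cohort(SyntheticConfig(rng_seed=11))


@pytest.fixture(scope="session")
def small_unilateral():
    """A small one-hemisphere cohort for cheap unit tests."""
    cfg = SyntheticConfig(
        n_subjects=3, grid_shape=(5, 5, 2), k_planted=3, bilateral=False, rng_seed=5
    )
    return generate_cohort(cfg)


@pytest.fixture(autouse=True)
def _fail_on_unexpected_nan():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


def random_labels(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """Random labeling guaranteed to use all k labels."""
    while True:
        lab = rng.integers(1, k + 1, size=n)
        if np.unique(lab).size == k:
            return lab
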