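import numpy as np
import pytest

from tboost.cohort import CohortTable
from tboost.simulate import GeneratorSpec, generate


def make_table(values, labels, feature_names=None, ids=None) -> CohortTable:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(values.shape[1])]
    if ids is None:
        ids = [f"s{i}" for i in range(values.shape[0])]
    return CohortTable(ids, feature_names, values, np.asarray(labels, dtype=int))


def random_table(rng, n_pos, n_neg, n_features) -> CohortTable:
    m = n_pos + n_neg
    values = rng.standard_normal((m, n_features))
    labels = np.concatenate([np.ones(n_pos, dtype=int), -np.ones(n_neg, dtype=int)])
    return make_table(values, labels)


@pytest.fixture
def tiny_table() -> CohortTable:
    """4 samples, 2 features, balanced labels; feature f0 separates at 7.5."""
    return make_table(
        [[5.0, 1.0], [6.0, 4.0], [10.0, 2.0], [11.0, 3.0]],
        [1, 1, -1, -1],
    )


@pytest.fixture(scope="session")
def discovery_cohort() -> CohortTable:
    """Default study-shaped synthetic discovery cohort (39 vs 13, 34 features)."""
    return generate(GeneratorSpec(seed=7))
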