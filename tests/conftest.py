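import numpy as np
import pytest

from metapick import Study, StudySet


@pytest.fixture
def four_unit_studies() -> StudySet:
    """Effects -1, 0, 1, 2 with unit variances; the worked selection example."""
    return StudySet.from_arrays([-1.0, 0.0, 1.0, 2.0], [1.0] * 4,
                                labels=["a", "b", "c", "d"])


@pytest.fixture
def single_study() -> StudySet:
    return StudySet([Study("only", 0.5, 0.25)])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230419)


def random_study_set(rng, k, equal_weights=False):
    """Random instance for greedy-vs-exhaustive comparisons."""
    effects = rng.normal(0, 1.5, k)
    if equal_weights:
        variances = np.full(k, float(rng.uniform(0.05, 1.0)))
    else:
        variances = rng.uniform(0.02, 1.5, k)
    return StudySet.from_arrays(effects, variances)
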