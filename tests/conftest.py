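import numpy as np
import pytest

from atrophy2d.imaging import extract_slices
from atrophy2d.phantom import desk_params, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240814)


@pytest.fixture(scope="session")
def small_cohort():
    """10 desk-preset phantom subjects (5 CU + 5 DAT), shared across tests."""
    return generate_cohort(5, 5, desk_params(), seed=3)


@pytest.fixture(scope="session")
def small_stacks(small_cohort):
    """Slice stacks with reference labels for the shared cohort."""
    return [
        extract_slices(v, labels=l, stride=5, subject_id=t.subject_id)
        for v, l, t in zip(small_cohort.volumes, small_cohort.label_volumes,
                           small_cohort.truths)
    ]
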