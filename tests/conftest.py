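import warnings

import numpy as np
import pytest

from coroqca.cohort import default_config, generate_cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_cohort():
    """The packaged 188-vessel study-condition cohort (seed 42)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_cohort(default_config())


@pytest.fixture(scope="session")
def default_table(default_cohort):
    return default_cohort.table
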