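import numpy as np
import pytest

import erlangcell as ec


@pytest.fixture(scope="session")
def truth_schedule():
    """Default proliferation truth: slow first division, faster later ones."""
    return ec.default_truth()


@pytest.fixture(scope="session")
def week_design():
    """First-week sampling design (days 3-7, five mice per day).

    The fast-proliferating clonotype is only informative through the first
    week (beyond that real populations hit resource competition the model
    deliberately excludes), so this is the design the fitting tests use.
    """
    return ec.ExperimentDesign(days=(3, 4, 5, 6, 7), mice_per_day=5)


@pytest.fixture(scope="session")
def week_dataset(truth_schedule, week_design):
    """One synthetic experiment under the default truth, fixed seed."""
    return ec.generate_dataset(truth_schedule, week_design, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
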