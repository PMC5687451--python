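import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_world():
    """A compact synthetic world shared by read-only tests (30x30 grid)."""
    from childmbg.synthetic import TruthConfig, simulate_world

    return simulate_world(TruthConfig(nrows=30, ncols=30, seed=11))


@pytest.fixture(scope="session")
def small_survey_bt(small_world):
    """A tabulated cluster survey on the small world."""
    from childmbg.birth_histories import tabulate_cbh
    from childmbg.synthetic import SurveyDesign, simulate_cbh

    cbh = simulate_cbh(small_world, SurveyDesign(n_clusters=150, mothers_per_cluster=15), seed=5)
    return tabulate_cbh(cbh)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
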