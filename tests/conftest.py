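import pytest

from msbra.evaluation import fit_all_posteriors
from msbra.synthetic_data import study_fixtures


@pytest.fixture(scope="session")
def fixtures():
    return study_fixtures()


@pytest.fixture(scope="session")
def posteriors(fixtures):
    """Full-length fits of the five meta-analytic models (shared)."""
    return fit_all_posteriors(seed=1, fixtures=fixtures)


@pytest.fixture(scope="session")
def quick_posteriors(fixtures):
    """Short chains for tests that only need plausible draw streams."""
    return fit_all_posteriors(seed=2, fixtures=fixtures, n_iter=8_000, burn_in=2_000)
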