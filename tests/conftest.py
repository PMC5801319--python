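import numpy as np
import pytest

from detectdim.fixtures import make_fixtures

FIXTURE_SEED = 7


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Toy fixture files plus the manifest of oracle values."""
    out = tmp_path_factory.mktemp("fixtures")
    manifest = make_fixtures(out, seed=FIXTURE_SEED)
    return out, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
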