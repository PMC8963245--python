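import numpy as np
import pytest

import pepgamd as pg
from pepgamd.fixtures import make_fixtures


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """Deterministic end-to-end bundle shared by integration tests."""
    outdir = tmp_path_factory.mktemp("bundle")
    manifest = make_fixtures(seed=20260929, outdir=outdir)
    return outdir, manifest


@pytest.fixture(scope="session")
def double_well():
    return pg.make_double_well(5.0, 2.0)


@pytest.fixture(scope="session")
def three_state_landscape():
    """The reference three-basin activation landscape used throughout."""
    return pg.make_three_state_landscape(
        [(8.6, 10.0), (11.1, 10.0), (15.3, 10.0)],
        [5.0, 4.4, 4.6],
        [0.9, 0.9, 0.9],
    )


@pytest.fixture(scope="session")
def peptide_system():
    return pg.make_toy_peptide_system(4, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
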