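import numpy as np
import pytest

import metastates as ms


@pytest.fixture(scope="session")
def small_connectome():
    return ms.make_structural_connectome(6, density=1.0, ceiling=0.2, seed=11)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Two-group, four-subject cohort at N=8; shared by cheap unit tests."""
    conn = ms.make_structural_connectome(8, density=0.6, ceiling=0.2, seed=5)
    regimes = [
        ms.GroupRegime(label="strong", n_subjects=2, coupling=0.4),
        ms.GroupRegime(label="weak", n_subjects=2, coupling=0.0),
    ]
    return ms.make_group_cohort(conn, regimes, t_points=120, tr_seconds=2.0, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
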