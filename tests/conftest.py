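import numpy as np
import pandas as pd
import pytest

from mycasm.synth import make_study_fixture


@pytest.fixture(scope="session")
def neutral_fixture():
    """30-sample neutral community (no selection, no dispersal)."""
    return make_study_fixture(
        "small", seed=3, replication=5, selection_strength=0.0, dispersal_rate=0.0
    )


@pytest.fixture(scope="session")
def selection_fixture():
    """30-sample strong host-specific selection (phylosymbiosis on)."""
    return make_study_fixture(
        "small", seed=3, replication=5, selection_strength=8.0,
        phylosymbiosis_strength=1.0, dispersal_rate=0.0,
    )


@pytest.fixture(scope="session")
def phylosym_fixture():
    """Strong-phylosymbiosis fixture used by the cophylogeny analyses.

    The medium preset (12 species) gives the one-individual-per-species
    designs enough host pairs to be informative.
    """
    return make_study_fixture(
        "medium", seed=6, replication=3, selection_strength=8.0,
        phylosymbiosis_strength=1.0, dispersal_rate=0.0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_table():
    from mycasm.core import CommunityTable

    return CommunityTable(
        pd.DataFrame(
            [[10, 5, 3, 0], [1, 1, 1, 1], [1, 2, 3, 4]],
            index=["s1", "s2", "s3"],
            columns=["t1", "t2", "t3", "t4"],
        )
    )
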