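import numpy as np
import pytest

import chromaccess as ca
from chromaccess.modeling import make_folds

# One shared paper-scale synthetic dataset for the expensive acceptance
# checks; session-scoped so the ~15 s generation cost is paid once.
PAPER_SEED = 11
SAMPLE_SEED = 7
FOLD_SEED = 1


@pytest.fixture(scope="session")
def paper_config():
    return ca.default_paper_like_config(seed=PAPER_SEED)


@pytest.fixture(scope="session")
def paper_dataset(paper_config):
    return ca.simulate_dataset(paper_config)


@pytest.fixture(scope="session")
def matrices_2000(paper_dataset):
    ds = paper_dataset
    mmax = ca.build_feature_matrix(ds.dhs, ds.dnase_track, ds.feature_tracks, "max")
    mavg = ca.build_feature_matrix(ds.dhs, ds.dnase_track, ds.feature_tracks, "avg")
    return (
        ca.sample_regions(mmax, 2000, SAMPLE_SEED),
        ca.sample_regions(mavg, 2000, SAMPLE_SEED),
    )


@pytest.fixture(scope="session")
def shared_folds(matrices_2000):
    return make_folds(matrices_2000[0].n_regions, 10, FOLD_SEED)


@pytest.fixture(scope="session")
def truth_table(paper_dataset):
    return paper_dataset.truth_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
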