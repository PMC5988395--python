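import numpy as np
import pandas as pd
import pytest

from tbinet.atlas import ConnectomePair


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_cohort_table(n_control=27, n_tbi=14, seed=0) -> pd.DataFrame:
    """Cohort covariate table with matched-group distributions."""
    r = np.random.default_rng(seed)
    n = n_control + n_tbi
    return pd.DataFrame(
        {
            "group": ["control"] * n_control + ["tbi"] * n_tbi,
            "age": r.uniform(8, 19, n),
            "sex": r.choice(["M", "F"], n),
            "fd_mean": r.lognormal(np.log(0.2), 0.4, n),
            "eddy_motion_mean": r.lognormal(np.log(0.5), 0.3, n),
        },
        index=pd.Index([f"s{i:02d}" for i in range(n)], name="subject"),
    )


def make_block_pair(n_per_block=10, n_blocks=4, fc_in=0.9, fc_out=0.1) -> tuple:
    """Noise-free block-structured structural/functional pair."""
    labels = np.repeat(np.arange(1, n_blocks + 1), n_per_block)
    same = labels[:, None] == labels[None, :]
    sc = same.astype(int)
    np.fill_diagonal(sc, 0)
    fc = np.where(same, fc_in, fc_out)
    np.fill_diagonal(fc, 1.0)
    return ConnectomePair(sc=sc, fc=fc), labels


@pytest.fixture
def cohort_table():
    return make_cohort_table()


@pytest.fixture
def block_pair():
    return make_block_pair()
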