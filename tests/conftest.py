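import warnings

import numpy as np
import pytest

from umed import UMED, synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


STUDY_FIT_KW = dict(ipt=512, candidate_sizes=(64, 96, 128),
                    D_L=8, N_L=6, N_G=5)


def fit_study_signal(seed):
    """Generate the reference synthetic recording and fit the detector."""
    sig, truth = synth.generate(**synth.study_conditions(), seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = UMED(sig, **STUDY_FIT_KW).fit()
    return sig, truth, res


@pytest.fixture(scope="session")
def study_fit():
    """One fitted synthetic recording shared across tests (seed 1)."""
    return fit_study_signal(seed=1)
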