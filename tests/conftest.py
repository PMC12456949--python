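import numpy as np
import pandas as pd
import pytest

from moralchoice import cohort
from moralchoice.trialgen import build_pair_pool, build_trialset


@pytest.fixture(scope="session")
def pool():
    return build_pair_pool()


@pytest.fixture(scope="session")
def trialset():
    return build_trialset(seed=7)


@pytest.fixture(scope="session")
def small_study():
    """8-subject two-session study used by several analysis tests."""
    cfg = cohort.CohortConfig(n_subjects=8)
    return cohort.generate_study(cfg, seed=11)


def simulate_single_cell(kappa, gamma, n, seed, context="gain", recipient="self"):
    """Choices for one condition cell on a fixed ratio-spread trial grid."""
    rng = np.random.default_rng(seed)
    ds = rng.integers(1, 20, size=n)
    dm = rng.integers(1, 100, size=n) / 5.0
    p = 1.0 / (1.0 + np.exp(-gamma * (kappa * ds - (1.0 - kappa) * dm)))
    return pd.DataFrame(
        {
            "context": context,
            "recipient": recipient,
            "delta_m": dm,
            "delta_s": ds,
            "choice": (rng.random(n) < p).astype(int),
        }
    )
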