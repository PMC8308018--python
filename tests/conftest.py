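import numpy as np
import pytest

from scoreprior import MCMCConfig, schools_fixture


@pytest.fixture(scope="session")
def schools():
    return schools_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(20210629)


@pytest.fixture
def quick_cfg():
    """Small-but-valid MCMC schedule for unit tests."""
    return MCMCConfig(n_iter=4000, burn_in=1000, thin=3, proposal_sd=0.5, seed=5)


def batch_se(draws: np.ndarray, n_batches: int = 20) -> float:
    """Batch-means Monte-Carlo standard error of the chain mean."""
    d = np.asarray(draws, dtype=float)
    m = len(d) // n_batches
    means = d[: m * n_batches].reshape(n_batches, m).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batches))
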