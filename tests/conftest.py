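import numpy as np
import pytest

from repsel.base_selectors import SelectorConfig
from repsel.ensemble import EnsembleConfig


@pytest.fixture
def light_selector_cfg():
    """Reduced-compute selector knobs so the suite stays fast; methods unchanged."""
    return SelectorConfig(rf_trees=50, boruta_max_iter=20)


@pytest.fixture
def light_ensemble_cfg(light_selector_cfg):
    return EnsembleConfig(selector=light_selector_cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_blocky_matrix(n, block_sizes, rho=0.9, n_noise=0, seed=0):
    """Gaussian design with equicorrelated blocks followed by independent noise."""
    rng = np.random.default_rng(seed)
    cols = []
    for size in block_sizes:
        base = rng.normal(size=n)
        lam = np.sqrt(rho)
        cols.append(
            lam * base[:, None] + np.sqrt(1 - rho) * rng.normal(size=(n, size))
        )
    if n_noise:
        cols.append(rng.normal(size=(n, n_noise)))
    return np.concatenate(cols, axis=1)
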