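import numpy as np
import pytest

import proxylearn as pl


@pytest.fixture(scope="session")
def fast_fit():
    """Reduced multi-start budget: plenty for the small fixtures here."""
    return pl.FitConfig(n_starts=6, seed=0)


@pytest.fixture(scope="session")
def small_dataset():
    """Tiny synthetic experiment shared across selection/stats tests."""
    design = pl.DesignConfig(n_subjects=4, n_control=2, n_tasks=2,
                             n_directions=2, n_trials=60, n_novision=18,
                             n_washout=12)
    return pl.generate_dataset(design, rng=np.random.default_rng(11))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
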