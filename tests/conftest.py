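import hypothesis
import numpy as np
import pytest

import countysae as cs

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None
)
hypothesis.settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config():
    """6x6 lattice, 7 years: quick but structurally complete."""
    return cs.SyntheticConfig(
        n_rows=6, n_cols=6, years=tuple(range(2007, 2014)), seed=101
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    return cs.generate_panel(small_config)


@pytest.fixture(scope="session")
def small_fit(small_panel):
    """A short BYM chain on the small panel, shared across tests."""
    panel, truth = small_panel
    model = cs.PretermBYMModel(panel, truth.structure)
    return model.fit(iterations=1200, burn_in=600, thin=3, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
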