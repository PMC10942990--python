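import numpy as np
import pytest

from mortgraph import SynthConfig, simulate_panel


@pytest.fixture(scope="session")
def small_synth():
    """Fast 6-country, 30-year, 20-age panel with 3 planted clusters."""
    cfg = SynthConfig(m=6, n_clusters=3, n_years=30, n_ages=20,
                      noise_sd=0.02)
    return simulate_panel(cfg, 7)


@pytest.fixture(scope="session")
def noiseless_synth():
    """Exact Lee-Carter panel: no observation noise, no walk, no jitter."""
    cfg = SynthConfig(m=4, n_clusters=2, n_years=24, n_ages=12,
                      cluster_drifts=(-1.5, 1.0), geo_centers=((60, 20), (47, 6)),
                      noise_sd=0.0, walk_sd=0.0, drift_jitter=0.0)
    return simulate_panel(cfg, 11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
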