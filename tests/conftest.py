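import numpy as np
import pytest

from hepatam import SimulationConfig, case_config


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Desk-scale configuration for fast unit tests."""
    cfg = case_config("primary", "cECM", True, rng_seed=7)
    cfg.grid_nodes_per_side = 41
    cfg.node_spacing = 2.0 / 41
    cfg.t_end = 2.0
    cfg.validate()
    return cfg


def short_case_config(tumor_type, ecm_type="cECM", polarized=True, seed=0,
                      days=5.0, dt=0.05):
    """Full-physics configuration at reduced duration for property tests."""
    cfg = case_config(tumor_type, ecm_type, polarized, rng_seed=seed)
    cfg.t_end = days
    cfg.dt = dt
    cfg.validate()
    return cfg
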