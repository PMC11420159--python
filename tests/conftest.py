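import numpy as np
import pytest

from earqc.simulate import SimConfig, generate_alpha_test, generate_nap


@pytest.fixture(scope="session")
def alpha_session():
    """Default-protocol alpha session with a reduced montage (fast)."""
    cfg = SimConfig(
        seed=123,
        scalp_channels=["T7", "T8", "FT11", "FT12", "Cz"],
        artifact_rate=0.0,
        contact_loss_prob=0.0,
    )
    return cfg, generate_alpha_test(cfg)


@pytest.fixture(scope="session")
def nap_session():
    """A 20-min nap; long enough for every canonical stage to appear."""
    cfg = SimConfig(protocol="nap", nap_len_s=1200, seed=42)
    return cfg, generate_nap(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
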