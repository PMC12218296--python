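import numpy as np
import pytest

from bgattgr.synthetic import FixtureConfig, generate_fingerprints


@pytest.fixture(scope="session")
def small_fixture():
    """A reduced planted-signal fixture: ~1:5 imbalance, narrow views.

    Small view widths keep matrix sizes down for unit tests that do not
    depend on the canonical 10,757-column fusion.
    """
    cfg = FixtureConfig(
        n_active=150,
        n_inactive=30,
        view_widths={"AP2D": 30, "CDKExt": 30, "KR": 40, "Morgan": 30, "RDKIT": 30},
        signal_bits=20,
        seed=11,
    )
    fused, labels = generate_fingerprints(cfg)
    return fused, labels


@pytest.fixture(scope="session")
def default_fixture():
    """The default study-condition fixture (600 compounds, width 10757)."""
    fused, labels = generate_fingerprints(FixtureConfig(seed=5))
    return fused, labels


@pytest.fixture
def rng():
    return np.random.default_rng(42)
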