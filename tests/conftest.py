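import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from bcrnet.simulate import SimConfig, simulate  # noqa: E402


@pytest.fixture(scope="session")
def default_sim():
    """One seeded default-condition simulation shared across the suite."""
    cfg = SimConfig()
    rep, truth = simulate(cfg, seed=7)
    return cfg, rep, truth


@pytest.fixture(scope="session")
def assigned_sim(default_sim):
    from bcrnet.evaluate import assign_all

    cfg, rep, truth = default_sim
    return cfg, rep, truth, assign_all(rep)
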