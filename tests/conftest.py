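import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset(tmp_path):
    """A tiny simulated dataset on disk: every pipeline input file."""
    from nucloc.simulate import SimConfig, write_dataset

    cfg = SimConfig(n_proteins=120, rng_seed=42)
    return cfg, write_dataset(tmp_path / "sim", cfg)
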