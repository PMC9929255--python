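import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from macnet.simulate import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The emulated discovery cohort at seed 1 (47 AMI + 20 ctrl, 2000 genes)."""
    return generate_cohort(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for cheap structural tests."""
    cfg = SyntheticConfig(
        seed=7,
        n_genes=250,
        n_modules=2,
        module_sizes=(40, 30),
        group_shift=(1.0, 0.0),
        subgroup_shift=(0.0, 1.5),
        trait_couplings={0: ("infarct_size", 0.6)},
        n_tfs=2,
        n_drugs=20,
        n_reversers=2,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
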