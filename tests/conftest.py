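import numpy as np
import pytest

from wmquant.gradients import default_gradient_table
from wmquant.phantom import REGION_DEFAULTS, PhantomSpec, build_phantom


@pytest.fixture(scope="session")
def gtab():
    """Two-shell acquisition: b=0, 30 @ 700, 64 @ 2000 s/mm^2."""
    return default_gradient_table()


@pytest.fixture(scope="session")
def gtab_low(gtab):
    return gtab.low_shell()


@pytest.fixture(scope="session")
def plic():
    return REGION_DEFAULTS["cst_plic"]


@pytest.fixture(scope="session")
def cst_cs():
    return REGION_DEFAULTS["cst_cs"]


@pytest.fixture(scope="session")
def frontal():
    return REGION_DEFAULTS["frontal_wm"]


@pytest.fixture(scope="session")
def small_phantom():
    """Noise-free 2-voxel-per-region phantom shared across tests."""
    return build_phantom(PhantomSpec(voxels_per_region=2, noise_sigma=0.0, seed=7))
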