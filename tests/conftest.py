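import numpy as np
import pytest

from qmripath import AIF, AcquisitionConfig, LesionSpec, generate_phantom

B_VALUES = np.array([0.0, 500.0, 1000.0, 1500.0, 2000.0])


@pytest.fixture(scope="session")
def b_values():
    return B_VALUES.copy()


@pytest.fixture(scope="session")
def noiseless_config():
    return AcquisitionConfig(seed=7, noise_sigma=0.0)


@pytest.fixture(scope="session")
def small_truth(noiseless_config):
    """~500-voxel ellipsoidal lesion with smooth heterogeneous maps."""
    spec = LesionSpec(semi_axes=(11.3, 11.3, 15.0))
    return generate_phantom(noiseless_config, spec)


@pytest.fixture(scope="session")
def dce_time_grid():
    return np.arange(70) * 5.0 / 60.0  # minutes


@pytest.fixture(scope="session")
def boxcar_aif(dce_time_grid):
    """Constant plasma concentration from t=0 (closed-form Tofts curve)."""
    return AIF(time=dce_time_grid, cp=np.full(dce_time_grid.size, 2.0))
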