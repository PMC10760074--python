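# Pin BLAS/OpenMP pools to the available cores before numpy loads;
# oversubscribed thread pools dominate runtime on small hosts.
import os

_n = str(os.cpu_count() or 1)
for _v in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(_v, _n)

import numpy as np
import pytest

from conedrive.photoreceptors import canine_sensitivities, default_grid
from conedrive.synth import synth_device


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def sensitivities(grid):
    return canine_sensitivities(grid)


@pytest.fixture(scope="session")
def device(grid):
    return synth_device(wavelengths=grid)


@pytest.fixture(scope="session")
def toy_device(grid):
    """3-primary device for oracle comparisons."""
    return synth_device(n_primaries=3, fwhm_nm=80.0, wavelengths=grid)
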