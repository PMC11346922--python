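import os

# pin BLAS threading before numpy loads: bit-reproducibility of trained
# models requires a fixed reduction order
for _var in ("OPENBLAS_NUM_THREADS", "OMP_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ[_var] = "1"

import numpy as np
import pytest

from rascl.phantoms import CohortConfig, as_cohort, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """24 noiseless 64x64 eyes (8 FTMH, 16 ERM), session-cached."""
    cfg = CohortConfig(
        n_ftmh=8, n_erm=16, image_height=64, image_width=64, speckle_sigma=0.0
    )
    volumes, manifest = generate_cohort(cfg, np.random.default_rng(42))
    return as_cohort(volumes, manifest)


@pytest.fixture(scope="session")
def noisy_cohort():
    """30 speckled 64x64 eyes (10 FTMH, 20 ERM), session-cached."""
    cfg = CohortConfig(n_ftmh=10, n_erm=20, image_height=64, image_width=64)
    volumes, manifest = generate_cohort(cfg, np.random.default_rng(7))
    return as_cohort(volumes, manifest)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
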