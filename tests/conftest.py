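import numpy as np
import pytest

from galda import (AcquisitionGrid, CohortConfig, PreprocessConfig,
                   build_default_library, run_preprocessing, simulate_cohort)

# Coarse grid for fast tests: same ppm span, 1/8 the points.  Linewidths
# (0.006 ppm FWHM) still cover ~1.5 grid steps, enough for peak placement.
COARSE_POINTS = 4096


@pytest.fixture(scope="session")
def coarse_grid():
    return AcquisitionGrid(n_points=COARSE_POINTS)


@pytest.fixture(scope="session")
def library():
    return build_default_library()


@pytest.fixture(scope="session")
def coarse_cohort(coarse_grid, library):
    """Default-size 39-sample cohort on the coarse grid."""
    return simulate_cohort(CohortConfig(seed=11), library, coarse_grid)


@pytest.fixture(scope="session")
def coarse_normalized(coarse_cohort):
    """Coarse cohort after track selection, baseline and normalization."""
    return run_preprocessing(coarse_cohort, PreprocessConfig(center=False))


@pytest.fixture(scope="session")
def tiny_cohort(coarse_grid, library):
    """Six samples (2 per group), for quick CV plumbing tests."""
    cfg = CohortConfig(n_per_group={"C": 3, "PD": 3, "T2D": 3}, seed=5)
    return simulate_cohort(cfg, library, coarse_grid)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
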