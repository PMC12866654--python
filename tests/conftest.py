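import numpy as np
import pytest

import ichvol as iv

SPHERE_R10_ML = 4.0 / 3.0 * np.pi  # 4/3 pi r^3 for r = 10 mm, in mL
ELLIPSOID_ML = 4.0 / 3.0 * np.pi * 30 * 20 * 10 / 1000.0  # (30, 20, 10) mm


@pytest.fixture(scope="session")
def sphere_1mm():
    """Digitized sphere, r = 10 mm at 1 mm isotropic spacing."""
    return iv.make_ellipsoid_mask((10, 10, 10), (1, 1, 1), (26, 26, 26))


@pytest.fixture(scope="session")
def ellipsoid_05mm():
    """Digitized (30, 20, 10) mm ellipsoid at 0.5 mm isotropic spacing."""
    return iv.make_ellipsoid_mask((30, 20, 10), (0.5, 0.5, 0.5), (130, 90, 50))


@pytest.fixture(scope="session")
def small_mask_cohort():
    """Eight fully rasterized phantoms with ground truth."""
    cfg = iv.CohortConfig(n_cases=8, seed=42)
    return iv.sample_cohort(cfg)
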