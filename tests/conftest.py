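import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from wearbench.synthetic_data import CohortConfig, ScannerConfig, generate_crown

#: Scaled-down crown resolution shared by mesh-heavy tests (fast but still
#: ~9k faces; full-resolution behavior is covered by the acceptance tests).
SMALL_CROWN_KW = dict(radial_segments=28, angular_segments=96, wall_segments=20)
TINY_CROWN_KW = dict(radial_segments=10, angular_segments=32, wall_segments=8)


def scaled_cohort_config(n_surfaces: int, seed: int, **overrides) -> CohortConfig:
    """Cohort config scaled for test runtime: coarser crowns, 100 um raster."""
    kwargs = dict(
        n_surfaces=n_surfaces,
        crown_radial_segments=28,
        crown_angular_segments=96,
        crown_wall_segments=20,
        profilometer=ScannerConfig(step_um=100.0),
        intraoral=ScannerConfig(capture_model="intraoral", noise_sd_um=5.0),
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


@pytest.fixture(scope="session")
def small_crown():
    return generate_crown(5, **SMALL_CROWN_KW)


@pytest.fixture(scope="session")
def tiny_crown():
    return generate_crown(3, **TINY_CROWN_KW)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
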