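import math

import numpy as np
import pytest

from photoxtal import diffmap, synthetic_data
from photoxtal.spectrokinetics import KineticScheme
from photoxtal.structio import UnitCell


@pytest.fixture(scope="session")
def toy_cell():
    return UnitCell(20.0, 22.0, 24.0, 90.0, 90.0, 90.0)


@pytest.fixture(scope="session")
def crystal_bundle():
    """Noise-free two-state toy crystal at alpha = 0.25 (shared, read-only)."""
    return synthetic_data.make_two_state_crystal(seed=11, alpha=0.25,
                                                 noise_frac=0.0)


@pytest.fixture(scope="session")
def noisy_crystal_bundle():
    """Two-state toy crystal at alpha = 0.30 with 3% amplitude noise."""
    return synthetic_data.make_two_state_crystal(seed=12, alpha=0.30,
                                                 noise_frac=0.03)


@pytest.fixture(scope="session")
def dark_fcalc(crystal_bundle):
    dark = crystal_bundle[0]
    return diffmap.calc_structure_factors(dark, 1.3)


@pytest.fixture(scope="session")
def study_scheme():
    return KineticScheme((13.0, 38.0, 162.0, math.inf))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
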