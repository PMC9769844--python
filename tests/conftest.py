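import numpy as np
import pytest
from hypothesis import settings

import oriscope as osc

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

GENOME = 4_600_000
WINDOW = 1_000


@pytest.fixture(scope="session")
def single_origin_spec():
    """Centered single origin with C/tau = 1 (origin/terminus ratio 2)."""
    return osc.ChromosomeSpec(GENOME, (GENOME // 2,), 1000.0, GENOME / 2 / 1000.0)


@pytest.fixture(scope="session")
def single_origin_profile(single_origin_spec):
    """Noiseless normalized copy-number profile of the single-origin model."""
    return osc.normalize_coverage(osc.expected_coverage(single_origin_spec, WINDOW))


@pytest.fixture(scope="session")
def single_origin_fit(single_origin_profile):
    return osc.loess_smooth(single_origin_profile)


@pytest.fixture(scope="session")
def triple_origin_spec():
    """Triple-origin chromosome at the package's realistic defaults."""
    return osc.ChromosomeSpec(GENOME, (365_000, 1_240_000, 3_925_000), 58_000.0, 40.0)


def flat_profile(n_windows=100, window=WINDOW, value=1.0):
    return osc.NormalizedProfile(
        n_windows * window, window, np.full(n_windows, value / n_windows)
    )
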