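import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from shgfiber import CohortParams, FiberImageParams, generate_cohort, generate_fiber_image


@pytest.fixture(scope="session")
def small_cohort():
    """A 13-vs-13 synthetic cohort with the default variance components."""
    return generate_cohort(CohortParams(seed=1))


@pytest.fixture(scope="session")
def high_snr_image():
    """One 512x512 high-SNR synthetic field of view at 10% truth fraction."""
    return generate_fiber_image(FiberImageParams(seed=7))
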