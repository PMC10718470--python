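import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_cohort():
    """A 60-patient calibrated cohort over all five levels."""
    from canalarea import CohortSpec, generate_cohort

    return generate_cohort(CohortSpec(n_patients=60, seed=42))


@pytest.fixture
def l1_pairs(rng):
    """(ipd, ap, manual) arrays drawn from the packaged L1 calibration."""
    from canalarea import CohortSpec, Level, generate_cohort

    df = generate_cohort(CohortSpec(n_patients=200, levels=(Level.L1,), seed=3))
    return (
        df["ipd_mm"].to_numpy(),
        df["ap_mm"].to_numpy(),
        df["canal_area_mm2"].to_numpy(),
    )
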