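import numpy as np
import pytest

from mealmodel.profiles import MmttProfile
from mealmodel.simulate import TrialConfig

SCHEDULE = np.array([-15.0, 0.0, 30.0, 60.0, 90.0, 120.0, 180.0])


@pytest.fixture
def example_profile() -> MmttProfile:
    """Hand-built well-formed subject-visit with all channels present."""
    return MmttProfile(
        subject_id="S001",
        visit="baseline",
        arm="placebo",
        times=SCHEDULE,
        glucose=np.array([9.1, 9.0, 12.0, 11.0, 10.0, 9.2, 8.8]),
        insulin=np.array([60.0, 62.0, 250.0, 280.0, 210.0, 150.0, 90.0]),
        cpeptide=np.array([1.0, 1.02, 1.9, 2.3, 2.1, 1.8, 1.3]),
        uge_0_3h=2.5,
        weight=90.0,
        height=170.0,
        age=55.0,
        sex="M",
        diabetic=True,
    )


@pytest.fixture
def noiseless_config() -> TrialConfig:
    return TrialConfig(noise_glucose_pct=0, noise_cpeptide_pct=0, noise_insulin_pct=0)
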