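import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from whdd.baseline import BASELINE_SAMPLES, BaselineProfile
from whdd.simulate import (
    ArtifactModel,
    INDOOR_PROTOCOL,
    indoor_preset,
    make_cohort,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


# Printed evaluation table of the device's static heart-rate comparison:
# (device after filtering, commercial wrist sphygmomanometer) per run.
TABLE6_HR_PAIRS = [
    (74, 81), (80, 78), (75, 80), (77, 75), (73, 80),
    (91, 88), (93, 91), (85, 78), (84, 81), (81, 80),
]

# Printed static body-temperature comparison: (device after filtering,
# commercial infrared ear thermometer) per run, degC.
TABLE7_TEMP_PAIRS = [
    (36.89, 36.3), (36.75, 36.4), (36.33, 36.4), (36.85, 36.4),
    (36.19, 36.5), (36.41, 37.0), (36.59, 36.4), (36.61, 36.5),
    (36.71, 36.4), (36.81, 36.4),
]


@pytest.fixture(scope="session")
def indoor_cohort():
    """The four-runner indoor treadmill cohort with default artifacts."""
    return make_cohort(indoor_preset(), INDOOR_PROTOCOL, ArtifactModel(),
                       seed=7)


@pytest.fixture(scope="session")
def strained_session(indoor_cohort):
    """An irregular-exerciser session that reported discomfort."""
    return next(s for s in indoor_cohort if s.runner.name == "user3")


def baseline_for(runner) -> BaselineProfile:
    """A completed baseline profile matching a simulated runner."""
    return BaselineProfile(
        relax_hr=runner.relax_hr,
        relax_gsr=runner.relax_gsr,
        n_samples=BASELINE_SAMPLES,
        hr_valid=True,
        gsr_valid=True,
        hr_attempts=1,
        gsr_attempts=1,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
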