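import numpy as np
import pytest

from venoppg.phases import PhaseTimeline
from venoppg.synth import NoiseParams, SubjectParams, generate_recording


@pytest.fixture(scope="session")
def timeline():
    return PhaseTimeline()


@pytest.fixture(scope="session")
def control_recording():
    """Noise-free control subject: normal venous emptying, elevation
    raises fingertip pulse amplitude, modest HR response."""
    params = SubjectParams(
        group_label="control", baseline_hr=80.0,
        phase_hr_effects={"Su": 1.9, "Pra": 4.3, "End": 4.1},
        transition_peak=4.1, venous_emptying_max_left=95.0,
        venous_emptying_max_right=95.0, hr_noise_sd=0.0)
    return generate_recording(params, NoiseParams.none(), seed=11)


@pytest.fixture(scope="session")
def venous_recording():
    """Noise-free venous-entrapment subject: low emptying plateau,
    sustained HR elevation during the manoeuvre."""
    params = SubjectParams(
        group_label="venous", baseline_hr=81.5,
        phase_hr_effects={"Su": 6.9, "Pra": 7.2, "End": 6.3},
        transition_peak=4.1, venous_emptying_max_left=55.0,
        venous_emptying_max_right=55.0, hr_noise_sd=0.0)
    return generate_recording(params, NoiseParams.none(), seed=12)


@pytest.fixture(scope="session")
def noisy_recording():
    """Control subject under realistic noise, artifacts and dropout."""
    params = SubjectParams(
        group_label="control", baseline_hr=80.0,
        phase_hr_effects={"Su": 1.9, "Pra": 4.3, "End": 4.1},
        transition_peak=4.1, hr_noise_sd=1.5)
    return generate_recording(params, NoiseParams(), seed=13)
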