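import numpy as np
import pytest

from gaitmix.synthetic import (
    CohortDesign,
    GaitSimParams,
    GroupSpec,
    PostureSimParams,
    TaskOffsets,
    simulate_accelerometer,
    simulate_keypoints,
)


@pytest.fixture(scope="session")
def clean_gait_params():
    """Perfectly periodic, symmetric, noise-free accelerometer parameters."""
    return GaitSimParams(
        timing_jitter_cv=0.0,
        amplitude_jitter_cv=0.0,
        asymmetry=0.0,
        noise_sd=0.0,
        rate_jitter_cv=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def clean_gait_sim(clean_gait_params):
    return simulate_accelerometer(clean_gait_params)


@pytest.fixture(scope="session")
def default_gait_sim():
    return simulate_accelerometer(GaitSimParams(seed=42))


@pytest.fixture(scope="session")
def clean_posture_params():
    """Noise-free walker with no dropout: truth and extraction must agree."""
    return PostureSimParams(keypoint_noise_sd=0.0, dropout_fraction=0.0, seed=5)


@pytest.fixture(scope="session")
def clean_posture_sim(clean_posture_params):
    return simulate_keypoints(clean_posture_params)


def make_group_spec(**gait_overrides) -> GroupSpec:
    return GroupSpec(
        gait=GaitSimParams(**gait_overrides),
        posture=PostureSimParams(walk_distance=3.0),
        gait_sd={"step_frequency": 0.15, "timing_jitter_cv": 0.02},
        posture_sd={"head_pitch_offset": 3.0},
        demographics={
            "age_years": (68.0, 7.0),
            "height_cm": (165.0, 8.0),
            "weight_kg": (65.0, 10.0),
        },
        male_fraction=0.5,
    )


@pytest.fixture(scope="session")
def small_design():
    spec = make_group_spec()
    return CohortDesign(
        n_control=2,
        n_csvd=2,
        control=spec,
        csvd=spec,
        tasks={"normal": TaskOffsets()},
        repetitions=1,
        seed=77,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
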