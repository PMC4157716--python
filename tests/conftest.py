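import warnings

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def worked_example():
    from earshare.simulate import generate_worked_example

    return generate_worked_example()


@pytest.fixture(scope="session")
def worked_profiles(worked_example):
    from earshare.io import build_plot_profiles
    from earshare.simulate import trial_records

    profiles, excluded = build_plot_profiles(trial_records(worked_example))
    assert excluded.empty
    return profiles


@pytest.fixture(scope="session")
def default_trial():
    from earshare.simulate import SyntheticTrialConfig, generate_trial

    return generate_trial(SyntheticTrialConfig(seed=20240917))


def fit_trial(tables, end_member_b="peduncle", bins=None):
    """Helper: generated tables -> fitted MixingResults (warnings silenced)."""
    from earshare.io import build_plot_profiles, profiles_to_frame
    from earshare.mixing import DEFAULT_BINS, GrainMixingModel
    from earshare.simulate import trial_records

    profiles, _ = build_plot_profiles(trial_records(tables))
    frame = profiles_to_frame(profiles)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return GrainMixingModel(frame, end_member_b, bins or DEFAULT_BINS).fit()
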