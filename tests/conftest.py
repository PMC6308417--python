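import warnings

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from insolegait.core import combine_feet
from insolegait.events import detect_contacts, moving_average, remove_outlier_strides
from insolegait.synthetic import default_profiles, generate_subject, noise_free


# grid-aligned zero-variance profile: every event lands exactly on a sample,
# so detected intervals are exactly constant (stride 1.10 s, swing 0.38 s,
# phase 180 deg at 100 Hz)
def exact_profile(**overrides):
    base = dict(
        stride_time_mean_s=(1.10, 1.10),
        swing_time_mean_s=(0.38, 0.38),
        phase_offset_deg=180.0,
        duration_s=60.0,
    )
    base.update(overrides)
    return noise_free(default_profiles()["YC"], **base)


@pytest.fixture(scope="session")
def exact_subject():
    """Noise-free, grid-aligned subject plus detected events for both feet."""
    left, right, truth = generate_subject(exact_profile(), seed=0)
    sm_l, sm_r = moving_average(left), moving_average(right)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ev_l = remove_outlier_strides(detect_contacts(sm_l))
        ev_r = remove_outlier_strides(detect_contacts(sm_r))
    return {
        "left": left,
        "right": right,
        "smooth_left": sm_l,
        "smooth_right": sm_r,
        "events_left": ev_l,
        "events_right": ev_r,
        "truth": truth,
        "total": combine_feet(sm_l, sm_r),
    }


@pytest.fixture(scope="session")
def noisy_subject():
    """Default YC profile subject (noise, turns) with detection applied."""
    prof = default_profiles()["YC"]
    left, right, truth = generate_subject(prof, seed=11)
    sm_l, sm_r = moving_average(left), moving_average(right)
    ev_l = remove_outlier_strides(detect_contacts(sm_l))
    ev_r = remove_outlier_strides(detect_contacts(sm_r))
    return {
        "left": left,
        "right": right,
        "events_left": ev_l,
        "events_right": ev_r,
        "truth": truth,
        "total": combine_feet(sm_l, sm_r),
        "profile": prof,
    }


@pytest.fixture(scope="session")
def small_cohort_features():
    """Feature table of a reduced default cohort (shared across test modules)."""
    from insolegait.pipeline import extract_cohort_features
    from insolegait.synthetic import generate_cohort

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cohort = generate_cohort(n_yc=6, n_amc=5, n_pd=5, seed=7)
        features = extract_cohort_features(cohort)
    return cohort, features
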