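import numpy as np
import pytest

from copmech.simulate import (GaitTemplateParams, SubjectProfile, SwayParams,
                              simulate_gait_initiation_trial,
                              simulate_standing_trial)


@pytest.fixture
def healthy_profile() -> SubjectProfile:
    return SubjectProfile(
        subject_id="H01", group="healthy", session="single",
        age=24, sex="M", bmi=23.0, mass=70.0,
        sway=SwayParams(theta_ml=1.0, theta_ap=1.0, sigma_ml=1.0, sigma_ap=1.0),
        gait=GaitTemplateParams(),
    )


@pytest.fixture
def quiet_profile() -> SubjectProfile:
    """Noise-free sway: the COP sits at its equilibrium offset."""
    return SubjectProfile(
        subject_id="H02", group="healthy", session="single",
        age=24, sex="F", bmi=22.0, mass=60.0,
        sway=SwayParams(sigma_ml=0.0, sigma_ap=0.0,
                        cop_offset_ml=12.0, cop_offset_ap=-7.0),
        gait=GaitTemplateParams(template_noise_sd=0.0),
    )


@pytest.fixture
def standing_trial(healthy_profile):
    return simulate_standing_trial(healthy_profile, duration=10.0, fs=200.0,
                                   seed=11)


@pytest.fixture
def gait_trial(healthy_profile):
    return simulate_gait_initiation_trial(healthy_profile, fs=500.0, seed=12)


def canonical_partition(labels) -> list:
    """Relabel cluster ids by first appearance so partitions compare."""
    mapping: dict = {}
    out = []
    for v in labels:
        v = int(v)
        if v == -1:
            out.append(-1)
            continue
        if v not in mapping:
            mapping[v] = len(mapping)
        out.append(mapping[v])
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
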