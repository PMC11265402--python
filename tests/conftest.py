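import numpy as np
import pytest

from myograsp import (
    AcquisitionConfig,
    ActivationProfile,
    ProtocolSpec,
    measure_mvic,
    preprocess_recording,
    simulate_mvic_calibration,
    simulate_session,
)


@pytest.fixture(scope="session")
def acq500():
    """Reduced-rate acquisition for fast unit tests."""
    return AcquisitionConfig(sampling_rate=500.0)


@pytest.fixture(scope="session")
def acq2k():
    return AcquisitionConfig()


@pytest.fixture(scope="session")
def clean_profile():
    """Noise-free, crosstalk-free activation profile (separability floor)."""
    return ActivationProfile(
        jitter_sd=0.0, baseline_offset=np.zeros(3), sensor_noise_sd=0.0
    )


@pytest.fixture(scope="session")
def short_protocol():
    return ProtocolSpec(task_duration=3.0, rest_duration=2.0, trim=0.5, n_trials=1)


@pytest.fixture(scope="session")
def small_envelope(acq500, short_protocol):
    """One short labeled session, preprocessed end to end at 500 Hz."""
    profile = ActivationProfile()
    calib, segments = simulate_mvic_calibration(profile, acq500, 1.0, seed=101)
    rec = simulate_session(short_protocol, profile, acq500, 1.0, seed=102)
    mvic = measure_mvic(calib, segments)
    return preprocess_recording(rec, mvic)
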