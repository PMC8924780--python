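import numpy as np
import pytest

from hrval.series import HRSeries
from hrval.synthetic import (
    DeviceErrorModel,
    Protocol,
    ProtocolSegment,
    SubjectParams,
    generate_cohort,
)


@pytest.fixture
def flat60_protocol() -> Protocol:
    return Protocol(segments=(ProtocolSegment("steady", 60.0, 60.0),))


@pytest.fixture
def two_step_protocol() -> Protocol:
    return Protocol(
        segments=(
            ProtocolSegment("low", 60.0, 60.0),
            ProtocolSegment("high", 120.0, 120.0),
        )
    )


@pytest.fixture
def quiet_subject() -> SubjectParams:
    return SubjectParams(baseline_hr=60.0, hr_response_tau=10.0, hrv_sd_ms=0.0, seed=7)


@pytest.fixture(scope="session")
def two_device_models() -> dict[str, DeviceErrorModel]:
    return {
        "tracker": DeviceErrorModel(
            sampling_mode="sparse",
            min_interval_s=1.0,
            max_interval_s=5.0,
            lag_s=3.0,
            bias_bpm=-2.0,
            noise_sd_bpm=3.0,
        ),
        "watch": DeviceErrorModel(
            sampling_mode="uniform",
            rate_hz=25.0,
            lag_s=7.0,
            bias_bpm=4.0,
            noise_sd_bpm=3.0,
        ),
    }


@pytest.fixture(scope="session")
def small_cohort():
    """Four-subject cohort with the two reference device models."""
    devices = {
        "tracker": DeviceErrorModel(
            sampling_mode="sparse", min_interval_s=1.0, max_interval_s=5.0,
            lag_s=3.0, bias_bpm=-2.0, noise_sd_bpm=3.0,
        ),
        "watch": DeviceErrorModel(
            sampling_mode="uniform", rate_hz=25.0,
            lag_s=7.0, bias_bpm=4.0, noise_sd_bpm=3.0,
        ),
    }
    return generate_cohort(4, devices, master_seed=20240101)


def series(values, start=0.0, mask=None, source_id="test") -> HRSeries:
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones(len(values), dtype=bool)
    return HRSeries(start_s=start, values=values, mask=np.asarray(mask, bool),
                    source_id=source_id)
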