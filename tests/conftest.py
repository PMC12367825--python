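import dataclasses

import numpy as np
import pytest

from avsynch.device_core import DeviceConfig
from avsynch.virtual_patient import (
    AmplitudeDistribution,
    ComboDistributions,
    PatientScript,
    VECTOR_COMBOS,
    make_synthetic_cohort,
)
from avsynch.waveform import BeatTiming


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def config():
    return DeviceConfig()


def make_flat_script(
    a3_mean=2.0,
    a3_sd=0.0,
    a4_mean=3.5,
    a4_sd=0.0,
    interval_ms=1000.0,
    variability=0.0,
    pac=0.0,
    pvc=0.0,
    timing=None,
    patient_id="TEST",
):
    """Script with identical distributions in every vector combination."""
    a3 = AmplitudeDistribution(
        mean=a3_mean, sd=a3_sd,
        min=a3_mean - 3 * a3_sd if a3_sd else a3_mean,
        max=a3_mean + 3 * a3_sd if a3_sd else a3_mean,
    )
    a4 = AmplitudeDistribution(
        mean=a4_mean, sd=a4_sd,
        min=a4_mean - 3 * a4_sd if a4_sd else a4_mean,
        max=a4_mean + 3 * a4_sd if a4_sd else a4_mean,
    )
    combos = {c: ComboDistributions(a3=a3, a4=a4) for c in VECTOR_COMBOS}
    return PatientScript(
        patient_id=patient_id,
        combos=combos,
        hourly_sinus_interval_ms=(interval_ms,),
        interval_variability_fraction=variability,
        pac_probability=pac,
        pvc_probability=pvc,
        timing=timing or BeatTiming(),
    )


@pytest.fixture
def flat_script():
    return make_flat_script()


@pytest.fixture(scope="session")
def small_cohort():
    return make_synthetic_cohort(6, seed=2024)


@pytest.fixture
def no_jitter_timing():
    return dataclasses.replace(BeatTiming(), a3_end_variation_sd_ms=0.0)
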