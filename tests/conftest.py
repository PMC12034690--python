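import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_spike_config():
    from ldstest.synth import AfterdischargeSpec, SpikeSimConfig, ToneResponseSpec

    return SpikeSimConfig(
        n_channels=2,
        spontaneous_rate=5.0,
        afterdischarge=AfterdischargeSpec(present=False),
        tone_response=ToneResponseSpec(onset_latency_s=0.008,
                                       response_duration_s=0.010,
                                       evoked_rate=150.0),
        seed=42,
    )


@pytest.fixture
def noise_free_abr_config():
    from ldstest.synth import ABRSimConfig

    return ABRSimConfig(n_sweeps=4, noise_sd_uv=0.0, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
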