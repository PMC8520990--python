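import pytest
from hypothesis import HealthCheck, settings

from cochlear_gain import IOFunction, ListenerProfile

# fixtures used inside @given are immutable value objects, so reuse across
# examples is safe; derandomize for reproducible CI-free runs
settings.register_profile(
    "ci",
    derandomize=True,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture
def io_fig() -> IOFunction:
    """The schematic broken-stick curve: 40 dB gain, slope 0.2 above a
    40-dB SPL breakpoint."""
    return IOFunction(gain_dB=40.0, compression_exponent=0.2,
                      breakpoint_dB=40.0)


@pytest.fixture
def listener(io_fig) -> ListenerProfile:
    """A calibrated listener: quiet threshold 12 dB SPL, off-frequency
    attenuation 9 dB, criterion SMR 0 dB."""
    return ListenerProfile.calibrated(
        "L1", 12.0, io_fig, off_freq_attenuation_dB=9.0,
        psychometric_spread_dB=4.0, run_noise_sd_dB=0.0)
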