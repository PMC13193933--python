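import pytest
from hypothesis import HealthCheck, settings

from rfdmodel import DEFAULT_PARAMS, InterferenceParams

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def defaults() -> InterferenceParams:
    """Weightlifter default parameter set (rfd0=15000, kappa=0.8, alpha=0.3, d0=2)."""
    return DEFAULT_PARAMS


#: Duration grid used for the model's tabulated predictions.
TABLE_DURATIONS = [0, 2, 5, 10, 20, 30, 60]

#: Tabulated rounded predictions (N/s and %) for the default parameters.
TABLE_RFD_ROUNDED = [15000, 15000, 7879, 4089, 3054, 3003, 3000]
TABLE_PCT_ROUNDED = [0, 0, 47, 73, 80, 80, 80]
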