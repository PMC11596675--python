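import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from nadomics import default_panel
from nadomics.synthetic_data import SimulationConfig

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture()
def sim_config():
    return SimulationConfig()


@pytest.fixture()
def noiseless_config():
    return SimulationConfig(technical_cv=0.0, biological_cv=0.0, injection_cv=0.0)


@pytest.fixture()
def tiny_peak_frame():
    """Minimal well-formed long-format peak frame (3 records, one sample)."""
    return pd.DataFrame({
        "sample_id": ["s1", "s1", "s1"],
        "channel_id": ["NAD+|12C", "NAD+|13C", "NADH|12C"],
        "area": [1000.0, 500.0, 250.0],
        "rt": [4.2, 4.2, 3.7],
        "role": ["unknown"] * 3,
    })
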