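import pytest
from hypothesis import HealthCheck, settings

from desyncflow import SimulationConfig, simulate_study

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cfg():
    """Compact cohort: fast enough for per-test reuse, all classes present."""
    return SimulationConfig(
        seed=42, n_participants=8,
        n_circadian_locked=6, n_sleepwake_driven=6, n_disrupted_amp=6,
        n_disrupted_mean=4, n_flat=12,
    )


@pytest.fixture(scope="session")
def small_study(small_cfg):
    return simulate_study(small_cfg)


@pytest.fixture(scope="session")
def noiseless_cfg():
    """All variance sources off: outputs are exact analytic sinusoids."""
    return SimulationConfig(
        seed=0, n_participants=3,
        n_circadian_locked=2, n_sleepwake_driven=2, n_disrupted_amp=2,
        n_disrupted_mean=1, n_flat=2,
        participant_sd=0.0, residual_sd=0.0, mesor_sd_log2=0.0,
        coupled_fraction=1.0,
    )


@pytest.fixture(scope="session")
def noiseless_study(noiseless_cfg):
    return simulate_study(noiseless_cfg)
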