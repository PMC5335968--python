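import warnings

import pytest

from ppgpulse import HeartRateEstimator, PipelineConfig
from ppgpulse.simulator import SimConfig, make_training_grid, simulate_recording


@pytest.fixture(scope="session")
def default_config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def training_grid():
    """The canonical clean/moderate/strong/overlap training grid."""
    return make_training_grid(duration_s=180.0, n_per_level=3, seed=42)


@pytest.fixture(scope="session")
def fitted_estimator(training_grid) -> HeartRateEstimator:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return HeartRateEstimator(random_state=0).fit(training_grid)


@pytest.fixture()
def clean_recording():
    """A short artifact-free recording with known truth."""
    cfg = SimConfig(
        duration_s=60.0, seed=5, ma_gain_linear=0.0, ma_gain_quadratic=0.0,
        ma_gain_independent=0.0, hr_start_bpm=90.0,
    )
    return simulate_recording(cfg)


@pytest.fixture()
def strong_recording():
    """A short recording dominated by cadence-coupled motion artifacts."""
    cfg = SimConfig(
        duration_s=60.0, seed=6, ma_gain_linear=4.0, ma_gain_quadratic=2.0,
        ma_gain_independent=0.0, hr_start_bpm=90.0,
    )
    return simulate_recording(cfg)
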