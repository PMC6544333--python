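import numpy as np
import pytest

from grangernet import GenusTimeSeriesTable, ProcessedSeries, RunConfig


@pytest.fixture
def small_table() -> GenusTimeSeriesTable:
    return GenusTimeSeriesTable(
        site_label="toy",
        taxa=["Bacteroides", "Prevotella", "Blautia"],
        days=np.arange(1, 6),
        values=np.array([
            [10.0, 12.0, 9.0, 11.0, 10.0],
            [3.0, 0.0, 4.0, 5.0, 2.0],
            [1.0, 2.0, 1.0, 0.0, 3.0],
        ]),
    )


@pytest.fixture
def random_table() -> GenusTimeSeriesTable:
    rng = np.random.default_rng(42)
    return GenusTimeSeriesTable(
        site_label="rand",
        taxa=[f"g{i:02d}" for i in range(10)],
        days=np.arange(50),
        values=rng.gamma(2.0, 50.0, size=(10, 50)),
    )


@pytest.fixture
def white_noise_series() -> ProcessedSeries:
    rng = np.random.default_rng(7)
    return ProcessedSeries(
        site_label="noise",
        taxa=[f"g{i}" for i in range(4)],
        matrix=rng.normal(size=(4, 120)),
    )


@pytest.fixture
def tiny_config() -> RunConfig:
    """Small-lag configuration for fast end-to-end tests."""
    return RunConfig(lags=3, short_range=(1, 1), long_range=(3, 3),
                     lambda_grid_size=20, seed=11)
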