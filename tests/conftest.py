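import numpy as np
import pandas as pd
import pytest

from meltshift import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """100-protein simulated TPP dataset with 10 stabilized spike-ins."""
    cfg = SimulationConfig(
        n_proteins=100,
        fraction_stabilized=0.10,
        fraction_destabilized=0.05,
        noise_cv=0.08,
        missing_rate=0.03,
        seed=42,
        effect_distribution=("constant", 6.0),
    )
    table, truths = simulate_dataset(cfg)
    return cfg, table, truths


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free, complete dataset: observations equal the model exactly."""
    cfg = SimulationConfig(
        n_proteins=30,
        fraction_stabilized=0.1,
        fraction_destabilized=0.1,
        noise_cv=0.0,
        missing_rate=0.0,
        seed=3,
        effect_distribution=("constant", 5.0),
    )
    table, truths = simulate_dataset(cfg)
    return cfg, table, truths


def curve_frame(temps, intensities, replicate=1):
    """Raw single-replicate series as the long per-protein frame."""
    return pd.DataFrame(
        {
            "temperature_c": np.asarray(temps, dtype=float),
            "intensity": np.asarray(intensities, dtype=float),
            "replicate": replicate,
        }
    )
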