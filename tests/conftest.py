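import pandas as pd
import pytest

from lipocount.config import (
    ClassSpec,
    ConditionSpec,
    SimulationConfig,
    default_config,
)


@pytest.fixture
def small_config() -> SimulationConfig:
    """The full study configuration at a small population size."""
    return default_config(seed=7, n_particles=200)


@pytest.fixture
def hdl_only_config() -> SimulationConfig:
    """A single-class, two-condition config for focused binding tests."""
    return SimulationConfig(
        classes=[
            ClassSpec(name="HDL", diameter_mean=12.28, diameter_sd=1.91,
                      multiplicity={1: 0.8, 2: 0.15, 3: 0.05})
        ],
        conditions=[
            ConditionSpec(name="control", propensity={"HDL": 0.099}),
            ConditionSpec(name="Torcetrapib", propensity={"HDL": 0.505}),
        ],
        n_particles=400,
        seed=11,
    )


@pytest.fixture
def hand_records() -> pd.DataFrame:
    """Six hand-built particles: two free, three binary, one ternary."""
    return pd.DataFrame(
        {
            "particle_id": [f"p{i}" for i in range(6)],
            "class": "HDL",
            "condition": "control",
            "time_min": 0.0,
            "diameter_long": [12.0, 11.0, 13.0, 12.5, 11.5, 12.2],
            "diameter_perp": [11.8, 10.9, 12.7, 12.1, 11.2, 12.0],
            "observed_protrusions": [0, 0, 1, 1, 2, 1],
            "ternary_partner": ["", "", "", "", "", "ldl-0001"],
        }
    )
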