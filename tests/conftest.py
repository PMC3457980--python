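import numpy as np
import pandas as pd
import pytest

from fetbead import ProbeProfileTable, SimulationConfig, simulate_experiment


@pytest.fixture
def tiny_table() -> ProbeProfileTable:
    """3 regular probes + 3 negative controls, 2 samples, hand-set values."""
    index = pd.Index(["p1", "p2", "p3", "n1", "n2", "n3"], name="probe_id")
    signal = pd.DataFrame(
        {"s1": [228.0, 128.0, 40.0, 20.0, 30.0, 34.0],
         "s2": [128.0, 228.0, 41.0, 22.0, 28.0, 34.0]},
        index=index,
    )
    detection = pd.DataFrame(
        {"s1": [0.01, 0.01, 0.9, 0.5, 0.5, 0.5],
         "s2": [0.02, 0.01, 0.9, 0.5, 0.5, 0.5]},
        index=index,
    )
    probe_class = pd.Series(
        ["regular"] * 3 + ["negative_control"] * 3, index=index, name="probe_class"
    )
    return ProbeProfileTable(signal, detection, probe_class)


@pytest.fixture(scope="session")
def small_experiment():
    """A seeded 1500-probe experiment with planted effects at default noise."""
    config = SimulationConfig(n_probes=1500, n_negative_controls=150, seed=42)
    table, truth = simulate_experiment(config)
    return config, table, truth


@pytest.fixture(scope="session")
def quiet_experiment():
    """Low-noise seeded experiment for recovery checks."""
    config = SimulationConfig(
        n_probes=1500, n_negative_controls=150, noise_log_sd=0.02, seed=7
    )
    table, truth = simulate_experiment(config)
    return config, table, truth
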