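import numpy as np
import pandas as pd
import pytest

from nrfomics import simulate


@pytest.fixture()
def rng():
    return np.random.default_rng(20100616)


@pytest.fixture()
def small_ratio_table():
    """Deterministic 20-protein ratio table with two planted effects."""
    config = simulate.SimulationConfig(
        n_proteins=20, n_animals_per_group=4, n_runs=4,
        true_fold_changes={"SIM00000": 0.5, "SIM00001": 2.0},
        cv=0.2, missing_run_rate=0.3, seed=42)
    return simulate.simulate_itraq(config)


@pytest.fixture()
def tiny_spot_table():
    """Two gels per group, four spots, no noise, planted 0.5 effect on spot 0."""
    return simulate.simulate_spot_table(
        n_spots=4, n_gels_per_group=2, effects={0: 0.5}, noise=0.0, seed=7)
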