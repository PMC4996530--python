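import numpy as np
import pandas as pd
import pytest

from famba import reference
from famba.synthetic import TrialConfig, simulate_trial, simulate_proteome


@pytest.fixture(scope="session")
def noiseless_trial():
    cfg = TrialConfig(tank_cv=0.0, system_effect=0.0, faeces_cv=0.0)
    return simulate_trial(cfg, seed=1)


@pytest.fixture(scope="session")
def default_trial():
    return simulate_trial(TrialConfig(), seed=7)


@pytest.fixture(scope="session")
def small_proteome():
    table, truth = simulate_proteome(n_proteins=300, seed=3)
    return table, truth


@pytest.fixture
def growth_table(default_trial):
    from famba.trial_metrics import sgr

    return pd.DataFrame(
        [
            {
                "tank_id": t.tank_id,
                "diet": t.diet,
                "system_id": t.system_id,
                "value": sgr(t),
            }
            for t in default_trial.tanks
        ]
    )
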