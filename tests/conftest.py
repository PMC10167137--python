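import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from vsmulti.preprocessing import CSV_COLUMNS
from vsmulti.synthetic_data import SimConfig, simulate_experiment

settings.register_profile("fixed", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("fixed")


def make_trials(rows):
    """Build a trial table from (participant, set_size, target, rt, correct,
    order) tuples with boilerplate covariates filled in."""
    recs = []
    for pid, set_size, target, rt, correct, order in rows:
        recs.append({
            "participant_id": pid, "group": "c", "gender": "f", "age": 10.0,
            "nystagmus": 0, "acuity_logmar": 0.0, "set_size": set_size,
            "target": target, "rt_s": rt, "correct": int(correct),
            "order": order,
        })
    return pd.DataFrame(recs, columns=CSV_COLUMNS)


@pytest.fixture(scope="session")
def default_experiment():
    """One default synthetic experiment, shared across tests."""
    return simulate_experiment(SimConfig(), seed=1)


@pytest.fixture(scope="session")
def preprocessed(default_experiment):
    from vsmulti.preprocessing import preprocess
    rt_table, cond_table = preprocess(default_experiment.trials)
    return rt_table, cond_table


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
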