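import numpy as np
import pandas as pd
import pytest

from foxnets import synthetic


@pytest.fixture(scope="session")
def small_config():
    return synthetic.ScenarioConfig(
        n_territories=2, patches_per_territory=3, group_size_range=(4, 6),
        survey_length_days=20, rng_seed=11)


@pytest.fixture(scope="session")
def small_scenario(small_config):
    return synthetic.simulate_scenario(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_visits(rows, territory="T1", season="spring", patch="P1"):
    """Visit table from (fox, start, end, day) tuples; times as strings."""
    recs = []
    for fox, start, end, day in rows:
        recs.append({"fox": fox, "patch": patch, "territory": territory,
                     "season": season, "start": pd.Timestamp(start),
                     "end": pd.Timestamp(end), "survey_day": day,
                     "start_only": False})
    return pd.DataFrame(recs)
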