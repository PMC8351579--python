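import pandas as pd
import pytest

import surveypower as sp


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic deployment (4 years x 2 sites) at the default params."""
    params = sp.SyntheticParams()
    intervals, env, moon = sp.generate_dataset(params, seed=1)
    env = sp.derive_env_features(env)
    return {"params": params, "intervals": intervals, "env": env, "moon": moon}


@pytest.fixture(scope="session")
def random_pool(default_dataset):
    """Peak-period pool with no environmental restriction."""
    scenario = sp.random_scenario()
    return scenario.filter_pool(
        default_dataset["intervals"], default_dataset["env"], default_dataset["moon"]
    )


@pytest.fixture()
def tiny_intervals():
    """Hand-written 2-date, 1-site interval table (evening bins)."""
    rows = []
    for date, flags in [("2016-02-01", [1, 0, 0, 0]), ("2016-02-02", [0, 1, 1, 0])]:
        for i, f in enumerate(flags):
            rows.append({"site_id": "P1", "date": pd.Timestamp(date),
                         "bin_start": 18 * 60 + 5 * i, "detected": f})
    return pd.DataFrame(rows)
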