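import numpy as np
import pandas as pd
import pytest

from dielaccess.density import TWO_PI, DielSample


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def vm_sample(rng):
    """Unimodal von Mises sample centred at midnight (0 rad)."""
    return DielSample("vm", "low", rng.vonmises(0.0, 2.0, 1000) % TWO_PI)


@pytest.fixture
def uniform_sample(rng):
    return DielSample("uniform", "low", rng.random(10_000) * TWO_PI)


@pytest.fixture
def small_events():
    """Nine detections at two sites, two species, with clustered triggers."""
    rows = [
        ("s1", "kob", "2017-03-01 06:00:00"),
        ("s1", "kob", "2017-03-01 06:10:00"),   # within 30 min of first
        ("s1", "kob", "2017-03-01 06:40:00"),   # 30 min after retained first
        ("s1", "warthog", "2017-03-01 06:05:00"),
        ("s2", "kob", "2017-03-01 06:01:00"),
        ("s2", "kob", "2017-03-01 09:00:00"),
        ("s1", "kob", "2017-03-02 06:00:00"),
        ("s2", "warthog", "2017-03-01 23:30:00"),
        ("s2", "warthog", "2017-03-01 23:45:00"),  # within 15 min
    ]
    df = pd.DataFrame(rows, columns=["site_id", "species", "timestamp"])
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["year"] = 2017
    return df


@pytest.fixture(scope="session")
def reference_scenario():
    from dielaccess.synthetic import make_reference_scenario

    return make_reference_scenario(seed=42)
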