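import numpy as np
import pandas as pd
import pytest

from headimpact import CohortConfig, simulate_cohort


def make_hit_log(rng, n_hits, players=("A", "B", "C")):
    """Random but well-formed hit log for oracle comparisons."""
    return pd.DataFrame({
        "player_id": rng.choice(players, n_hits),
        "session_type": rng.choice(["practice", "game", "other"], n_hits,
                                   p=[0.6, 0.35, 0.05]),
        "linear_g": rng.lognormal(3.2, 0.7, n_hits),
        "rotational_rad_s2": rng.lognormal(7.4, 0.6, n_hits),
        "azimuth_deg": rng.uniform(-180.0, 180.0, n_hits),
        "elevation_deg": rng.uniform(-90.0, 90.0, n_hits),
    })


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_log(rng):
    return make_hit_log(rng, 500)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (38 players, planted dose-response)."""
    return simulate_cohort(CohortConfig(seed=11))
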