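import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # pp_oracle helper

import cansurv


@pytest.fixture(scope="session")
def unit_lt():
    """Life table with no background mortality (weights all 1)."""
    return cansurv.unit_life_table()


@pytest.fixture(scope="session")
def gm_lt():
    """Realistic Gompertz-Makeham male life table with calendar improvement."""
    return cansurv.make_life_table(sex="male", country="SE",
                                   calendar_drift=0.005)


def random_small_dataset(rng: np.random.Generator, n_max: int = 10,
                         truncated: bool = True):
    """Random risk-interval dataset of size <= n_max for oracle checks."""
    from cansurv.relsurv import PeriodDataset

    n = int(rng.integers(1, n_max + 1))
    age = rng.uniform(30, 89, n)
    date = rng.uniform(1985, 2005, n)
    if truncated:
        entry = np.where(rng.random(n) < 0.3, rng.uniform(0.0, 1.5, n), 0.0)
    else:
        entry = np.zeros(n)
    exit_ = entry + rng.uniform(0.05, 6.0, n)
    event = rng.random(n) < 0.6
    return PeriodDataset(age, date, entry, exit_, event)
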