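import logging

import numpy as np
import pytest
from hypothesis import settings

import ranksexplained as rx

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

logging.getLogger("ranksexplained").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def toy_rt():
    return rx.toy_rate_table()


@pytest.fixture(scope="session")
def s1_small():
    """Small colon-like cohort with known truth (linear proportional age effect)."""
    spec = rx.scenario_s1(n=500, seed=42)
    return spec, rx.assemble_dataset(spec)


@pytest.fixture(scope="session")
def s1_model(s1_small):
    spec, ds = s1_small
    model = rx.fit(ds, spec.rate_table, rx.ExcessModelSpec(3, (rx.CovariateTerm("agez"),)))
    return model


def random_survival_data(rng, n, cens_frac=0.3, tie_frac=0.0):
    """Arbitrary small survival dataset with labels, for oracle comparisons."""
    import pandas as pd

    times = rng.exponential(2.0, n) + 0.05
    if tie_frac > 0:
        k = int(tie_frac * n)
        times[:k] = np.round(times[:k], 1) + 0.05
    d = (rng.random(n) > cens_frac).astype(int)
    cause = np.where(d == 1, np.where(rng.random(n) < 0.7, "cancer", "other"), "none")
    df = pd.DataFrame({"time": times, "status": d, "cause": cause})
    return rx.SurvivalDataset(df, cause_col="cause")
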