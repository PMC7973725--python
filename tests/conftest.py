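import numpy as np
import pandas as pd
import pytest

import hurdlemap as hm


def make_tracts(
    n: int = 20,
    pop_over16: float = 10_000,
    seed: int = 0,
    years=(2015,),
    counts=None,
) -> pd.DataFrame:
    """Hand-built minimal tract table with controllable populations/counts."""
    rng = np.random.default_rng(seed)
    pop = np.full(n, int(pop_over16))
    df = pd.DataFrame(
        {
            "tract_id": [f"A-{i:05d}" for i in range(n)],
            "region": "A",
            "x": rng.uniform(0, 20, n),
            "y": rng.uniform(0, 20, n),
        }
    )
    df["pop_men_under16"] = 0
    df["pop_women_under16"] = 0
    df["pop_men_16to64"] = pop // 2
    df["pop_men_65plus"] = 0
    df["pop_women_16to64"] = pop - pop // 2
    df["pop_women_65plus"] = 0
    df["pop_over16"] = pop
    df["pop_total"] = pop
    df["deprivation"] = rng.normal(size=n)
    df["deprivation_q"] = hm.quintile_categorise(df["deprivation"].to_numpy()) if n >= 5 else 1
    df["dist_centre"] = rng.uniform(0, 15, n)
    for yr in years:
        y = counts if counts is not None else np.zeros(n, dtype=int)
        df[f"cases_MND_{yr}"] = y
        df[f"cases_ALS_{yr}"] = y
        df[f"cases_PMA_{yr}"] = 0
        df[f"cases_PLS_{yr}"] = 0
    return df


@pytest.fixture(scope="session")
def small_landscape():
    return hm.generate_landscape(50, seed=1)


@pytest.fixture(scope="session")
def default_simulation(small_landscape):
    truth = hm.default_truth()
    sim = hm.simulate_disease(small_landscape, truth, range(2013, 2019), seed=2)
    return truth, sim
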