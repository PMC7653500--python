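import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import fertigrade as fg

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ref_system():
    return fg.reference_system()


@pytest.fixture()
def small_cohort_frame():
    """Three complete records with both outcomes represented."""
    return pd.DataFrame(
        {
            "age": [30.0, 41.0, 36.0],
            "bmi": [21.0, 27.5, 19.0],
            "fsh": [6.0, 12.0, 8.0],
            "afc": [14, 4, 9],
            "amh": [3.1, 0.9, 2.2],
            "oocytes": [12, 3, 8],
            "emt": [11.5, 7.0, 9.5],
            "pregnant": [1, 0, 1],
        }
    )


@pytest.fixture(scope="session")
def calibrated_cohort():
    """Medium table-calibrated synthetic cohort shared across tests."""
    return fg.generate_cohort(fg.default_config(20000, seed=4))


def make_invariant_cohort(n=2000, seed=5):
    """Grid-valued two-cluster cohort on which rebuilds are invariant.

    Values sit on a two-point grid with well-separated outcome rates, so
    every fold-complement reproduces the same cut, weights and grade
    threshold.
    """
    rng = np.random.default_rng(seed)
    vals = np.where(np.arange(n) % 2 == 0, 2, 20).astype(float)
    y = (rng.random(n) < np.where(vals > 10, 0.6, 0.05)).astype(int)
    return fg.CohortTable(
        pd.DataFrame({"afc": vals, "pregnant": y}), provenance="cleaned"
    )


def invariant_build_config(**over):
    base = dict(
        candidates=["afc"],
        forced=(),
        n_trees=25,
        n_grades=2,
        seed=1,
        cleaning_rules=[
            r for r in fg.default_cleaning_rules() if r.indicator == "afc"
        ],
    )
    base.update(over)
    return fg.BuildConfig(**base)
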