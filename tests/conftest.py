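import numpy as np
import pandas as pd
import pytest

from coraldemog import bayes_models as bm
from coraldemog import synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def quick_mcmc():
    """Short chains for tests where full-length sampling adds nothing."""
    return bm.MCMCSettings(chains=2, iterations=1000, warmup=300, thin=2, seed=7)


def make_colony_table(
    n_per_stratum: int = 80,
    seed: int = 0,
    bleach_rate: float = 0.5,
    bleach_slope: float = 0.0,
    pm_rate: float = 0.05,
    partial_capture_rate: float = 0.107,
) -> pd.DataFrame:
    """Small two-site, three-period survey table with one genus per habitat pair."""
    size_models = {}
    for genus, (mean_area, cv, skew) in {
        "Pocillopora": (66.42, 0.51, -0.03),
        "Turbinaria": (708.47, 0.31, -0.29),
    }.items():
        for habitat in ("inshore", "offshore"):
            size_models[(genus, habitat)] = synth.solve_size_params(
                mean_area, cv, skew, taxon=genus, habitat=habitat,
                n_per_stratum=n_per_stratum,
            )
    from scipy.special import logit

    condition_models = {
        genus: synth.ConditionModel(
            bleach_intercept=float(logit(bleach_rate)),
            bleach_slope=bleach_slope,
            pm_intercept=float(logit(pm_rate)),
            partial_capture_rate=partial_capture_rate,
        )
        for genus in ("Pocillopora", "Turbinaria")
    }
    design = synth.SurveyDesign(
        sites={"West Isle": "inshore", "East Isle": "offshore"},
        surveys=[(2010, 10), (2016, 4), (2018, 10)],
    )
    return synth.generate_colony_table(size_models, condition_models, design, seed=seed)


@pytest.fixture(scope="session")
def colony_table():
    return make_colony_table()
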