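import numpy as np
import pandas as pd
import pytest

from malnowcast import anthro, simulate
from malnowcast.config import GeneratorConfig


@pytest.fixture(scope="session")
def lms_table():
    return anthro.LmsReferenceTable.synthetic()


@pytest.fixture(scope="session")
def small_world():
    cfg = GeneratorConfig(
        n_strata=6, n_months=24, clusters_per_survey=8,
        children_per_cluster=10, survey_fraction=0.4, seed=42,
    )
    return simulate.generate_world(cfg)


@pytest.fixture(scope="session")
def small_surveys(small_world):
    children, meta = simulate.generate_all_surveys(small_world)
    children = anthro.add_whz(children, small_world.reference)
    children = anthro.apply_exclusions(children)
    return children, meta


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_pairs(rng, n, with_obs_ci=True):
    """Randomised prediction/observation pair sets for metric oracles."""
    y = rng.uniform(0.0, 0.4, n)
    yhat = np.clip(y + rng.normal(0, 0.05, n), 0.0, 1.0)
    half95 = rng.uniform(0.0, 0.08, n)
    half80 = half95 * 0.6
    df = pd.DataFrame({
        "stratum_id": [f"S{i}" for i in range(n)],
        "month": np.arange(n),
        "outcome": "gam_wfh",
        "source": "holdout",
        "point": yhat,
        "ci95_low": np.clip(yhat - half95, 0, 1),
        "ci95_high": np.clip(yhat + half95, 0, 1),
        "ci80_low": np.clip(yhat - half80, 0, 1),
        "ci80_high": np.clip(yhat + half80, 0, 1),
        "y": y,
    })
    if with_obs_ci:
        ohalf = rng.uniform(0.0, 0.08, n)
        df["y_ci95_low"] = np.clip(y - ohalf, 0, 1)
        df["y_ci95_high"] = np.clip(y + ohalf, 0, 1)
        df["y_ci80_low"] = np.clip(y - 0.6 * ohalf, 0, 1)
        df["y_ci80_high"] = np.clip(y + 0.6 * ohalf, 0, 1)
    return df
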