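import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import metaoccu as mo

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def toy_covariates(patch_ids):
    """Minimal valid covariate frame cycling through the category levels."""
    sizes = ["small", "medium", "large"]
    comps = ["clustered", "discrete"]
    vegs = ["none", "moderate", "abundant"]
    mats = ["pasture", "tussock"]
    rows = {
        "size": [sizes[i % 3] for i in range(len(patch_ids))],
        "composition": [comps[i % 2] for i in range(len(patch_ids))],
        "vegetation": [vegs[i % 3] for i in range(len(patch_ids))],
        "matrix": [mats[i % 2] for i in range(len(patch_ids))],
        "isolation_m": [10.0 + 5.0 * i for i in range(len(patch_ids))],
    }
    return pd.DataFrame(rows, index=pd.Index(patch_ids, name="patch_id"))


def dataset_from_presence(presence_by_season, n_surveys=4):
    """Build a dataset whose naive per-season status matches the given
    (n_patches, n_seasons) 0/1/NaN array: 1 -> first survey detects,
    0 -> all-zero season, NaN -> all surveys missing."""
    status = np.asarray(presence_by_season, dtype=float)
    n, T = status.shape
    det = np.zeros((n, T, n_surveys))
    det[status == 1, 0] = 1.0
    det[np.isnan(status)] = np.nan
    ids = [f"T{i:03d}" for i in range(n)]
    return mo.MetapopDataset(ids, det, toy_covariates(ids))


@pytest.fixture
def toy_dataset():
    """Two patches, 3 seasons x 4 surveys, one detection each for patch A."""
    det = np.zeros((2, 3, 4))
    det[0, :, 0] = 1.0
    det[1, 2, 3] = np.nan
    return mo.MetapopDataset(["A", "B"], det, toy_covariates(["A", "B"]))


@pytest.fixture(scope="session")
def study_patches():
    return mo.generate_patches(mo.SimulationConfig(n_patches=289, seed=11))


@pytest.fixture(scope="session")
def sim_dataset(study_patches):
    """A study-sized simulated dataset under the default truth."""
    dataset, truth_table = mo.simulate_dataset(
        mo.study_truth(), study_patches, n_seasons=3, n_surveys=4, seed=12
    )
    return dataset, truth_table
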