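import numpy as np
import pandas as pd
import pytest

from chemopop import synthetic_data as sd


@pytest.fixture(scope="session")
def small_cohort():
    """Compact cohort reused across read-only tests."""
    cfg = sd.CohortConfig(
        n_subpops=4, n_regions=2, individuals_per_subpop=20,
        n_tags=60, snps_per_tag=2, fst_target=0.1,
        n_metabolites=40, redundancy_factor=3.0, n_latent_pathways=5,
        dropout_rate=0.05, seed=42,
    )
    return sd.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_grouping(small_cohort):
    return small_cohort.metadata["subpopulation"]


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def make_distance(points: np.ndarray, ids=None) -> pd.DataFrame:
    """Euclidean distance matrix helper for structure tests."""
    from scipy.spatial.distance import pdist, squareform

    ids = ids if ids is not None else [f"e{i}" for i in range(len(points))]
    return pd.DataFrame(squareform(pdist(np.atleast_2d(points))), index=ids, columns=ids)
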