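import numpy as np
import pandas as pd
import pytest

from cnvcerna.simulate import SimulationConfig, SyntheticCohort, generate_cohort


SMALL_CONFIG = SimulationConfig(
    n_samples=80,
    n_mrna=40,
    n_lncrna=8,
    n_mirna=10,
    n_driver_genes=4,
    n_weakened_pairs=4,
    targets_per_mirna=3,
    seed=5,
)


@pytest.fixture(scope="session")
def small_cohort() -> SyntheticCohort:
    """A small planted cohort shared by the slower integration tests."""
    return generate_cohort(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_cohort_dir(small_cohort, tmp_path_factory):
    from cnvcerna.simulate import write_cohort

    d = tmp_path_factory.mktemp("cohort")
    paths = write_cohort(small_cohort, d)
    return paths


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_expression(rng, n_feat=50, n_samp=20, missing=0.0, prefix="G"):
    vals = rng.gamma(2.0, 2.0, size=(n_feat, n_samp))
    if missing:
        mask = rng.random(vals.shape) < missing
        vals = np.where(mask, np.nan, vals)
    return pd.DataFrame(
        vals,
        index=[f"{prefix}{i:03d}" for i in range(n_feat)],
        columns=[f"S{i:03d}" for i in range(n_samp)],
    )
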