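import numpy as np
import pandas as pd
import pytest

from adhdml import synthdata as sd


@pytest.fixture(scope="session")
def adhd200_phenotypes() -> pd.DataFrame:
    """Phenotype table generated from the published training-set composition."""
    return sd.generate_phenotypes(sd.adhd200_template(seed=7))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny two-site cohort with a strong planted connectivity effect."""
    cfg = sd.CohortConfig(
        sites=[
            sd.SiteSpec("S1", n_td=14, n_adhd_c=8, n_adhd_i=4),
            sd.SiteSpec("S2", n_td=12, n_adhd_c=6, n_adhd_i=6),
        ],
        R=6,
        T=64,
        planted_edges=[(0, 1, 1.5)],
        voxel_grid=(4, 4, 4),
        voxel_block=((0, 3), (0, 3), (0, 3)),
        voxel_shared_effect=0.4,
        morph_effect=[("lh_posteriorcingulate_ThickStd", 1.0)],
        seed=11,
    )
    return cfg, sd.generate_cohort(cfg, with_voxels=True)
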