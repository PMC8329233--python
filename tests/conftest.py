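import numpy as np
import pandas as pd
import pytest

import retdeconv as rd


@pytest.fixture(scope="session")
def clean_reference():
    """Small reference with unambiguous marker structure and no profile jitter."""
    cfg = rd.SimConfig(
        n_celltypes=3,
        n_genes=1200,
        cells_per_type=150,
        markers_per_type=10,
        marker_fc=500.0,
        profile_jitter_sd=0.0,
        ctdeg_fraction=0.0,
        conditions=[("control", 5), ("advanced", 5)],
        seed=11,
    )
    sc, truth = rd.simulate_reference(cfg)
    return cfg, sc, truth


@pytest.fixture(scope="session")
def small_study():
    """Reference + bulk with jittered profiles and planted effects."""
    cfg = rd.SimConfig(
        n_celltypes=4,
        n_genes=1500,
        cells_per_type=100,
        markers_per_type=15,
        marker_fc=200.0,
        profile_jitter_sd=0.1,
        ctdeg_fraction=0.2,
        ctdeg_fc=0.25,
        conditions=[("control", 10), ("advanced", 10)],
        proportions_by_condition={
            "control": [0.40, 0.25, 0.20, 0.15],
            "advanced": [0.16, 0.33, 0.28, 0.23],
        },
        proportion_noise=1000.0,
        seed=7,
    )
    sc, bulk, truth = rd.simulate_study(cfg)
    return cfg, sc, bulk, truth


@pytest.fixture()
def two_group_counts():
    """Dense random NB counts with two balanced groups, for DE-engine tests."""
    rng = np.random.default_rng(42)
    n1 = n2 = 10
    genes = [f"g{i}" for i in range(300)]
    mu = rng.gamma(2.0, 50.0, size=300)
    disp = 0.1
    counts = rng.negative_binomial(1 / disp, 1 / (1 + disp * mu[:, None]), size=(300, n1 + n2))
    cols = [f"s{i}" for i in range(n1 + n2)]
    df = pd.DataFrame(counts, index=genes, columns=cols)
    cond = pd.Series(["a"] * n1 + ["b"] * n2, index=cols)
    return rd.BulkMatrix(counts=df, conditions=cond)
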