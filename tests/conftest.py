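import numpy as np
import pandas as pd
import pytest

import crossplast as cp


@pytest.fixture(scope="session")
def small_dataset() -> cp.SimDataset:
    """Small default-structure dataset with planted DE in both species."""
    cfg = cp.SimConfig(
        n_genes_a=1200,
        n_genes_b=1150,
        frac_de_a=0.25,
        frac_de_b_per_timepoint=0.03,
        rho_shared=0.5,
        seed=5,
    )
    return cp.simulate_dataset(cfg)


@pytest.fixture()
def tiny_counts() -> cp.CountMatrix:
    rng = np.random.default_rng(0)
    genes = [f"g{i}" for i in range(50)]
    samples = [f"s{i}" for i in range(6)]
    counts = pd.DataFrame(
        rng.poisson(60, size=(50, 6)), index=genes, columns=samples
    )
    meta = pd.DataFrame(
        {
            "condition": ["ctl"] * 3 + ["trt"] * 3,
            "block": ["b1", "b2", "b1", "b2", "b1", "b2"],
        },
        index=samples,
    )
    return cp.CountMatrix(counts=counts, sample_meta=meta)
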