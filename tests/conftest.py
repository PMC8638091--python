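import numpy as np
import pandas as pd
import pytest

import dclink as dl


@pytest.fixture
def rng():
    return np.random.default_rng(20210)


@pytest.fixture
def small_matrix(rng):
    """8 genes x 6 samples of iid normals."""
    genes = [f"G{i}" for i in range(1, 9)]
    samples = [f"S{i}" for i in range(1, 7)]
    return pd.DataFrame(rng.standard_normal((8, 6)), index=genes, columns=samples)


@pytest.fixture(scope="session")
def planted_cohort():
    """Cohort with two planted DC pairs, one DE gene, one prognosis pair."""
    cfg = dl.SimConfig(
        n_subjects=60,
        n_extra_tumor=150,
        n_genes=40,
        planted_dc_pairs=[
            ("G0001", "G0002", 0.8, 0.0),
            ("G0003", "G0004", 0.0, 0.8),
        ],
        planted_de_genes=[("G0010", 2.0)],
        null_pairs=30,
        prognosis_pairs=[(("G0003", "G0004"), 3.0)],
        seed=17,
    )
    return dl.generate_cohort(cfg)
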