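import numpy as np
import pytest

import rfmri_sexdiff as rsd


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_spec():
    """Single-site desk fixture for fast unit tests."""
    return rsd.default_cohort_spec(
        n_sites=1,
        cell_sizes=((5, 5, 5, 5),),
        grid_dims=(12, 12, 8),
        n_timepoints=80,
    )


@pytest.fixture
def tiny_bold(rng):
    """6x6x4x40 random volume used against brute-force metric oracles."""
    mask = np.ones((6, 6, 4), dtype=bool)
    data = rng.standard_normal((6, 6, 4, 40))
    return rsd.BoldImage(data=data, mask=mask, voxel_size=3.0, tr=2.0)


@pytest.fixture
def pheno_table():
    """Two-site 2x2 phenotype table with realized motion summaries."""
    spec = rsd.default_cohort_spec(n_sites=2, cell_sizes=((8, 8, 8, 8),) * 2)
    table = rsd.generate_phenotypes(spec, rsd.default_sites(2))
    table["mfd"] = table["target_mfd"]
    return table
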