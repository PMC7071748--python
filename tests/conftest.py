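import zlib

import numpy as np
import pytest

from aspugwas.simdata import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def null_dataset():
    """One subgroup, no planted effects, perfect imputation (for calibration)."""
    cfg = SimConfig(
        n_samples_per_subgroup=[2000],
        n_variants=300,
        seed=11,
        imputation_quality_range=(1.0, 1.0),
    )
    panels, phenos = generate_dataset(cfg)
    return cfg, panels, phenos


@pytest.fixture()
def rng(request):
    # independent, deterministic stream per test (stable across processes)
    name_seed = zlib.crc32(request.node.name.encode()) % (2**31)
    return np.random.default_rng([20240917, name_seed])
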