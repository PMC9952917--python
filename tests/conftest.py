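import numpy as np
import pandas as pd
import pytest

from refstab.simulate import GeneratorConfig, generate_study


@pytest.fixture(scope="session")
def default_study():
    return generate_study(GeneratorConfig(), seed=11)


@pytest.fixture(scope="session")
def analysis_table(default_study):
    """Replicate-merged default study with undetermined samples excluded."""
    return default_study.analysis_table()


@pytest.fixture(scope="session")
def wide_meta(analysis_table):
    wide = analysis_table.wide()
    meta = analysis_table.meta_frame().loc[wide.index]
    return wide, meta


def two_group_matrix(rng, noise_sds, group_shifts, n_per_group=20):
    """Samples x genes Cq matrix for two groups with known gene properties."""
    k = len(noise_sds)
    groups = np.repeat(["A", "B"], n_per_group)
    X = np.empty((2 * n_per_group, k))
    for i, (sd, shift) in enumerate(zip(noise_sds, group_shifts)):
        base = 26.0 + i
        X[:, i] = base + rng.normal(0, sd, 2 * n_per_group)
        X[groups == "B", i] += shift
    cols = [f"g{i}" for i in range(k)]
    return pd.DataFrame(X, columns=cols), groups
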