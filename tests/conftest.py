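import numpy as np
import pytest

from neuroscore.synthdata import SyntheticCohortSpec, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Two-subject (one novice e=0.05, one expert e=0.95) single-run cohort."""
    spec = SyntheticCohortSpec(
        n_subjects_per_group=1, grid_dims=(16, 16, 16), n_runs=1,
        expertise=(0.05, 0.95), seed=7,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def planted_dm_stack():
    """40 condensed DMs in 3 well-separated planted groups + truth labels."""
    rng = np.random.default_rng(0)
    protos = rng.normal(size=(3, 276))
    rows, truth = [], []
    for g, size in enumerate((14, 13, 13)):
        for _ in range(size):
            rows.append(protos[g] + rng.normal(0, 0.3, 276))
            truth.append(g)
    return np.array(rows), np.array(truth)


def brute_force_correlation_dm(patterns):
    """Independent oracle: looped per-pair 1 - Pearson r."""
    n = patterns.shape[0]
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            r = np.corrcoef(patterns[i], patterns[j])[0, 1]
            out.append(1.0 - r)
    return np.array(out)
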