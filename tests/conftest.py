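import numpy as np
import pytest

from pdrpnet.simulate import SimulationConfig, simulate_cohort
from pdrpnet.ssm import derive_pattern, preprocess_profiles


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic derivation cohort (33 HC + 33 PD, 95 ROIs)."""
    return simulate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_pattern(default_cohort):
    cohort, _truth = default_cohort
    return derive_pattern(preprocess_profiles(cohort))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_toy_cohort(n_sub, n_roi, seed=0, groups=None):
    """Small random cohort with strictly positive activities."""
    from pdrpnet.cohort import CohortMatrix

    r = np.random.default_rng(seed)
    act = np.exp(r.normal(4.0, 0.3, (n_sub, n_roi)))
    if groups is None:
        half = n_sub // 2
        groups = ("HC",) * half + ("PD",) * (n_sub - half)
    return CohortMatrix(
        activities=act,
        roi_ids=tuple(f"R{j}" for j in range(n_roi)),
        subject_ids=tuple(f"s{i}" for i in range(n_sub)),
        group_labels=tuple(groups),
    )
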