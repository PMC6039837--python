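import numpy as np
import pytest

from megnet_vns.synthcohort import CohortSpec, generate_cohort
from megnet_vns.workflow import cohort_features, features_to_wide

#: Scaled-down study conditions used by the end-to-end tests: fewer channels
#: and shorter runs than a real MEG session, same epoching, bands and cost.
E2E_SPEC = dict(
    n_per_group=(9, 14, 14),
    n_channels=24,
    n_modules=4,
    fs_hz=128.0,
    run_length_s=24.0,
    control_run_length_s=24.0,
    n_runs=3,
    seed=20180618,
)


@pytest.fixture(scope="session")
def e2e_theta_features():
    """Full synthetic cohort run through connectivity + graph stages (theta band).

    Returns (wide feature table indexed by subject, per-run tidy table).
    Session-scoped: the heavy simulate->PLV->graph chain runs once.
    """
    cohort = generate_cohort(CohortSpec(**E2E_SPEC))
    per_run = cohort_features(
        cohort, epoch_len_s=3.0, cost=0.10, n_restarts=20, seed=11, bands=["theta"]
    )
    wide = features_to_wide(per_run)
    return wide, per_run


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
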