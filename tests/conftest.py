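import numpy as np
import pandas as pd
import pytest

from cordbmi import synthetic, trajectory
from cordbmi.growth import LMSReference


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort (seed 1), shared across the suite."""
    return synthetic.generate_cohort(seed=1)


@pytest.fixture(scope="session")
def lms_ref():
    return LMSReference(synthetic.generate_reference())


@pytest.fixture(scope="session")
def standard_windows(default_cohort):
    return trajectory.build_standard_windows(default_cohort.growth)


@pytest.fixture(scope="session")
def trajectory_assignments(default_cohort, standard_windows, lms_ref):
    pct_windows = [w for w in standard_windows if w.age_lo >= 24.0 - 1e-9]
    matrix = trajectory.window_average(
        default_cohort.growth, pct_windows, kind="BMIPCT", ref=lms_ref
    )
    matrix = trajectory.impute_adjacent(matrix)
    assignments = trajectory.collapse_groups(
        trajectory.classify_trajectories(matrix, seed=0)
    )
    return matrix, assignments


def planted_block_frame(n, sizes, rho, seed):
    """Block-factor metabolite matrix with known membership, for recovery tests."""
    rng = np.random.default_rng(seed)
    cols, data, truth = [], [], []
    for b, m in enumerate(sizes):
        f = rng.standard_normal(n)
        for j in range(m):
            if rho > 0:
                x = np.sqrt(rho) * f + np.sqrt(1 - rho) * rng.standard_normal(n)
            else:
                x = rng.standard_normal(n)
            data.append(x)
            cols.append(f"b{b}_m{j:02d}")
            truth.append(b)
    X = pd.DataFrame(np.column_stack(data), columns=cols)
    return X, np.array(truth)
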