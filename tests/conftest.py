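"""Shared seeded fixtures: phantom cohorts reused across the suite.

Cohort parameters here are the study conditions of the synthetic
experiments; they are fixed (sizes, openness values, master seeds) so
every test sees the same data.
"""

from __future__ import annotations

import numpy as np
import pytest

import chromatex as cx

MASTER_SEED = 11


@pytest.fixture(scope="session")
def calibration_cohort():
    """Two strongly separated cohorts: openness 0.1 vs 0.9, n=20, 256 px."""
    return cx.synth_cohort(
        [0.1, 0.9], 20, cx.PhantomSpec(), seed=MASTER_SEED,
        labels=["closed_like", "open_like"],
    )


@pytest.fixture(scope="session")
def calibration_descriptors(calibration_cohort):
    return cx.cohort_descriptors(calibration_cohort)


@pytest.fixture(scope="session")
def theta_grid_cohort():
    """20-condition openness grid, n=5 each, 128 px phantoms."""
    thetas = np.linspace(0.05, 0.95, 20)
    return cx.synth_cohort(
        thetas, 5, cx.PhantomSpec(shape=(128, 128)), seed=MASTER_SEED + 1,
        labels=[f"c{i:02d}" for i in range(len(thetas))],
    )


@pytest.fixture(scope="session")
def theta_grid_descriptors(theta_grid_cohort):
    return cx.cohort_descriptors(theta_grid_cohort)


@pytest.fixture(scope="session")
def small_two_class_cohort():
    """Moderately separated two-class cohort for degradation studies."""
    return cx.synth_cohort(
        [0.2, 0.8], 10, cx.PhantomSpec(shape=(128, 128)),
        seed=MASTER_SEED + 2, labels=["closed_like", "open_like"],
    )


@pytest.fixture(scope="session")
def single_phantom():
    return cx.synth_nucleus(cx.PhantomSpec(openness=0.4, seed=MASTER_SEED))


def random_descriptor_frame(rng, n, shift=None):
    """A synthetic n x 104 descriptor table (random, optionally shifted)."""
    import pandas as pd

    X = rng.standard_normal((n, 104))
    if shift is not None:
        X = X + shift
    return pd.DataFrame(X, columns=cx.descriptor_names())
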