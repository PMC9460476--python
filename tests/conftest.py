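"""Shared fixtures: small synthetic sessions and trained classifiers."""

from __future__ import annotations

import numpy as np
import pytest

import driftadapt as da
from driftadapt.activities import Activity


@pytest.fixture(scope="session")
def small_session() -> da.SessionDataset:
    """Two-day drifting feature session, 6 trials/day (fast protocol runs)."""
    drift = da.default_drift_config(seed=7, days=(1, 2), shift_magnitudes=(0.0, 2.5),
                                    cov_scales=(1.0, 0.9))
    return da.simulate_feature_session(
        drift=drift, n_days=2, trials_per_day=6, days=(1, 2)
    )


@pytest.fixture(scope="session")
def day1_session() -> da.SessionDataset:
    """Single-day stationary session used for classifier fixtures."""
    drift = da.default_drift_config(seed=3, days=(1,), shift_magnitudes=(0.0,),
                                    cov_scales=(1.0,))
    return da.simulate_feature_session(
        drift=drift, n_days=1, trials_per_day=12, days=(1,)
    )


@pytest.fixture(scope="session")
def separable_two_class():
    """Two well-separated Gaussian classes (d=4, n=200/class, 3 sigma apart)."""
    rng = np.random.default_rng(11)
    n = 200
    x = np.vstack([rng.normal(0.0, 1.0, (n, 4)), rng.normal(3.0, 1.0, (n, 4))])
    y = [Activity.WALK] * n + [Activity.STAIR_ASCENT] * n
    return x, y


@pytest.fixture(scope="session")
def trained_two_class(separable_two_class):
    x, y = separable_two_class
    return da.train(x, y, da.NetConfig(seed=5)), x, y
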