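"""Shared fixtures.

The expensive parameter-recovery experiment (5 seeded fits on the
n=2000 recovery fixture) is session-scoped and shared by the clustering
and attribution acceptance checks.
"""

from __future__ import annotations

import numpy as np
import pytest

import spatialmix as sm

# study conditions of the recovery experiment
RECOVERY_SPEC = dict(n_units=2000, k_domains=4, m_features=60)
RECOVERY_SEEDS = (0, 1, 2, 3, 4)
RECOVERY_FIT = dict(
    n_clusters=4, epochs=150, batch_size=512, use_image=True, patch_size=16
)


def run_recovery(seed: int):
    """One seeded end-to-end run on the recovery fixture; returns
    (ground-truth dataset, preprocessed dataset, fitted estimator)."""
    ds = sm.generate(sm.SyntheticSpec(seed=seed, **RECOVERY_SPEC))
    dsp = sm.preprocess(ds)
    est = sm.SpatialGMVAE(random_state=seed, **RECOVERY_FIT)
    est.fit(dsp)
    return ds, dsp, est


@pytest.fixture(scope="session")
def recovery_runs():
    return {seed: run_recovery(seed) for seed in RECOVERY_SEEDS}


@pytest.fixture(scope="session")
def small_fit():
    """A cheap fitted model on a 500-unit fixture for interface tests."""
    ds = sm.generate(sm.SyntheticSpec(n_units=500, k_domains=3, m_features=30, seed=7))
    dsp = sm.preprocess(ds)
    est = sm.SpatialGMVAE(
        n_clusters=3, epochs=25, batch_size=256, use_image=True,
        patch_size=16, random_state=7,
    )
    est.fit(dsp)
    return ds, dsp, est


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
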