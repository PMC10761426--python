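import dataclasses

import numpy as np
import pandas as pd
import pytest

from metabotyper.synthetic_data import (FactorBlock, GroundTruth,
                                        PlatformSpec, default_ground_truth,
                                        known_answer_fixture, simulate_study)


@pytest.fixture(scope="session")
def small_truth() -> GroundTruth:
    """A fast two-platform, three-factor study for pipeline-level tests."""
    platforms = (
        PlatformSpec("mini_lc", 40, (FactorBlock(0, 8), FactorBlock(1, 6)),
                     family_size=8),
        PlatformSpec("mini_gc", 24, (FactorBlock(2, 6),), family_size=8),
    )
    means = np.array([
        [-0.1, -0.3, -0.3],
        [0.0, 0.1, 2.0],
        [0.4, 1.4, 0.2],
    ])
    return GroundTruth(
        n_factors=3, cluster_sizes=(20, 8, 12),
        cluster_factor_means=means, platform_specs=platforms,
        missing_rate=0.02, seed=7)


@pytest.fixture(scope="session")
def small_study(small_truth):
    return simulate_study(small_truth)


@pytest.fixture(scope="session")
def default_study():
    """The full default five-platform study (seed 0); simulated once."""
    truth = default_ground_truth(seed=0)
    bundle, latent = simulate_study(truth)
    return truth, bundle, latent


@pytest.fixture(scope="session")
def tiny_bundle():
    return known_answer_fixture()


def noiseless_truth(seed: int = 0) -> GroundTruth:
    """Degenerate one-cluster truth: no noise, no drift, no missingness."""
    platforms = (
        PlatformSpec("flat", 10, (FactorBlock(0, 4),), drift_a=0.0,
                     drift_b=0.0, family_size=3),
    )
    return GroundTruth(
        n_factors=1, cluster_sizes=(12,),
        cluster_factor_means=np.zeros((1, 1)),
        platform_specs=platforms, noise_sd=0.0, missing_rate=0.0,
        qc_noise_sd=0.0, n_qc=5, seed=seed)


def with_params(truth: GroundTruth, **kw) -> GroundTruth:
    return dataclasses.replace(truth, **kw)
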