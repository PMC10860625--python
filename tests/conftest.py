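import numpy as np
import pytest

from chordrsa import (
    ChordConfig,
    PatternGroundTruth,
    RDM,
    SkillParams,
    simulate_force_trial,
)

SCANNER_LABELS = ("145", "234", "134", "125", "235")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def chord_145():
    return ChordConfig("145")


@pytest.fixture
def perfect_trial(chord_145):
    """Noise-free, coupling-free trial: instructed plateau exactly 2.5 N."""
    return simulate_force_trial(chord_145, SkillParams(), seed=0)


@pytest.fixture
def euclidean_rdm(rng):
    """A Euclidean-embeddable 5-condition RDM from random latent points."""
    from scipy.spatial.distance import pdist

    pts = rng.standard_normal((5, 3))
    return RDM(SCANNER_LABELS, pdist(pts, metric="sqeuclidean"))


@pytest.fixture
def pattern_gt(euclidean_rdm):
    return PatternGroundTruth(
        true_rdm_contra=euclidean_rdm,
        homotopy_level=0.0,
        signal_scale_by_hemisphere=(1.0, 1.0),
        noise_covariance=0.25,
        n_voxels=100,
        n_runs=4,
        n_residual_samples=120,
    )
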