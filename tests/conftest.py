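import numpy as np
import pytest

from rsnlong.cohort import BlobSpec, CohortDesign, GroundTruth, make_network_maps


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_design():
    """Two subjects, one timepoint, small grid: the smallest legal cohort."""
    return CohortDesign(
        group_sizes=((1,), (1,)),
        age_means=((5.0,), (6.0,)),
        age_sds=((0.1,), (0.1,)),
        grid_dims=(12, 12, 8),
        n_volumes=100,
        seed=7,
    )


@pytest.fixture
def small_design():
    """Reduced two-group, three-timepoint longitudinal design for fast
    integration tests."""
    return CohortDesign(
        group_sizes=((4, 4, 4), (4, 4, 4)),
        age_means=((5.0, 11.0, 17.0), (5.5, 11.3, 17.5)),
        age_sds=((0.3, 0.3, 0.3), (0.3, 0.3, 0.3)),
        grid_dims=(16, 16, 10),
        n_volumes=60,
        seed=11,
    )


def two_blob_truth(design, noise_sd=0.5, motion_coupling=0.0, seed=3):
    """A minimal two-network ground truth on a small grid."""
    mask = np.ones(design.grid_dims, dtype=bool)
    spec = BlobSpec(radius_xy=2.6, radius_z=2.2, exponent=8, min_support=40,
                    min_separation=6.0)
    maps = make_network_maps(design.grid_dims, mask, 2, spec, seed=seed)
    rng = np.random.default_rng(seed + 1)
    patterns = rng.standard_normal((6, int(mask.sum())))
    patterns /= patterns.std(axis=1, ddof=1, keepdims=True)
    return GroundTruth(
        network_maps=maps,
        network_names=("net_a", "net_b"),
        mask=mask,
        amp_intercept=np.ones((2, 2)),
        amp_slope=np.zeros((2, 2)),
        subject_sd=0.05,
        noise_sd=noise_sd,
        motion_coupling=motion_coupling,
        motion_patterns=patterns,
    )


@pytest.fixture
def tiny_truth(tiny_design):
    return two_blob_truth(tiny_design)
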