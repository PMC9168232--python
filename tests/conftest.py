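import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from joingcla.popgraphs import ConnectivityFeatures, OmicsTable, ScanManifest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_manifest():
    """Five scans over three subjects, both classes present."""
    return ScanManifest(
        scan_ids=("s1_a", "s1_b", "s2_a", "s3_a", "s3_b"),
        subject_ids=("sub1", "sub1", "sub2", "sub3", "sub3"),
        labels=(0, 0, 1, 1, 1),
    )


@pytest.fixture
def tiny_features(rng, tiny_manifest):
    """One modality of random connectivity features for the tiny manifest."""
    r = 6
    return ConnectivityFeatures(
        "dti", rng.standard_normal((tiny_manifest.n_scans, r * (r - 1) // 2)), r
    )


@pytest.fixture
def tiny_omics(rng):
    return OmicsTable(
        "met",
        rng.standard_normal((3, 8)),
        ("sub1", "sub2", "sub3"),
        tuple(f"f{i}" for i in range(8)),
    )
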