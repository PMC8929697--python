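import numpy as np
import pytest

from famsplit.msa_io import Alignment
from famsplit.synthetic import FamilySpec, generate_family


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_alignment():
    return Alignment(
        "tiny",
        ("s1", "s2", "s3"),
        ("ACDEF", "ACDEG", "WYWYW"),
    )


@pytest.fixture(scope="session")
def two_cluster_family():
    """Two well-separated clusters, splittable at p=25/q=50 with 10/2 minima."""
    return generate_family(
        FamilySpec(cluster_sizes=(15, 15), within_identity=0.40, seed=11)
    )


@pytest.fixture(scope="session")
def bridged_family():
    """The same two clusters joined by one chimeric bridge sequence."""
    return generate_family(
        FamilySpec(cluster_sizes=(15, 15), within_identity=0.40, n_bridges=1, seed=11)
    )


@pytest.fixture(scope="session")
def outlier_family():
    """29 mutually similar sequences plus one unrelated outlier."""
    return generate_family(
        FamilySpec(
            k_clusters=1, cluster_sizes=(29,), within_identity=0.80, n_outliers=1, seed=5
        )
    )
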