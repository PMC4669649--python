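import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import augcall

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def easy_bundle():
    """Well-separated common-SNP panel: the easy regime for the caller."""
    cfg = augcall.SimulationConfig(
        n_samples=200, n_snps=8, n_known=60, maf_spec=0.2, seed=11
    )
    return augcall.generate_panel(cfg)


@pytest.fixture(scope="session")
def default_geometry_model():
    """A ClusterModel at the default synthetic cluster geometry."""
    geom = augcall.ClusterGeometry()
    return augcall.ClusterModel(
        snp_id="snpX",
        means=geom.means,
        covs=geom.covariances(),
        counts=np.array([10, 10, 10]),
        source="G1-direct",
    )
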