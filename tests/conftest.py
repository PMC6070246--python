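import pytest
from hypothesis import HealthCheck, settings

from lncpair.gene_models import GeneModel, GenomicInterval
from lncpair.simulate import SimulationConfig, simulate_bundle

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def worked_gene() -> GeneModel:
    """Plus-strand gene with exons [100,200) and [400,500), CDS [150,450)."""
    return GeneModel(
        gene_id="G1",
        span=GenomicInterval("chr1", 100, 500, "+"),
        exons=(
            GenomicInterval("chr1", 100, 200, "+"),
            GenomicInterval("chr1", 400, 500, "+"),
        ),
        cds_start=150,
        cds_end=450,
    )


@pytest.fixture(scope="session")
def bundle():
    """One full synthetic dataset shared across read-only tests."""
    return simulate_bundle(SimulationConfig(seed=3))
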