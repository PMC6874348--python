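import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def demo_genes():
    from trnamod.simulate import demo_reference_genes

    return demo_reference_genes()


@pytest.fixture(scope="session")
def ala_gene(demo_genes):
    return next(g for g in demo_genes if g.gene_id == "tRNA-Ala-AGC-1-1")
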