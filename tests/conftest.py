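import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted-motif study shared across tests (seed fixed)."""
    from splicemotifs.simulate import build_enrichment_dataset

    return build_enrichment_dataset(n_events=60, n_background=400, seed=11)


@pytest.fixture()
def tiny_genome():
    from splicemotifs.genome import GenomeSequence

    return GenomeSequence({"c1": "AACG"})
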