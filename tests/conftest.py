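import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def paper_bundle():
    """Paper-like synthetic input bundle, shared across the session."""
    from sfpage.simulate import paper_like_bundle

    return paper_like_bundle(seed=1)


@pytest.fixture(scope="session")
def aged_catalog(paper_bundle):
    """Catalog assembled from the paper-like bundle with ages attached."""
    from sfpage import assemble_catalog, assign_ages

    cat = paper_bundle["catalog"]
    c = assemble_catalog(cat.list_a, cat.list_b)
    return assign_ages(c, cat.age_table, cat.exceptions)
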