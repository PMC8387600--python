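import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from covidkg.fixtures import (  # noqa: E402
    FixtureSpec,
    gen_annotated_corpus,
    gen_policy_corpus,
    mini_schema,
    toy_embeddings,
    toy_lexdb,
    worked_example_graph,
)
from covidkg.schema import build_bkg_schema, build_hipaa_schema  # noqa: E402


@pytest.fixture(scope="session")
def bkg_schema():
    return build_bkg_schema()


@pytest.fixture(scope="session")
def hipaa_schema():
    return build_hipaa_schema()


@pytest.fixture(scope="session")
def small_schema():
    return mini_schema()


@pytest.fixture(scope="session")
def worked_graph():
    return worked_example_graph()


@pytest.fixture(scope="session")
def lexdb():
    return toy_lexdb()


@pytest.fixture(scope="session")
def embeddings8():
    return toy_embeddings(8, 7)


@pytest.fixture(scope="session")
def policy_corpus():
    return gen_policy_corpus(FixtureSpec(seed=7, n_docs=20))


@pytest.fixture(scope="session")
def annotated_corpus():
    return gen_annotated_corpus(FixtureSpec(seed=7, n_docs=50))
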