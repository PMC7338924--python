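import pytest

from vapelens import simulate
from vapelens.sentiment import LexiconScorer
from vapelens.taxonomy import Post


@pytest.fixture(scope="session")
def taxonomies():
    """(ecig, health, flavor) fixture taxonomies, validated."""
    return simulate.fixture_taxonomies()


@pytest.fixture(scope="session")
def ecig_tax(taxonomies):
    return taxonomies[0]


@pytest.fixture(scope="session")
def health_tax(taxonomies):
    return taxonomies[1]


@pytest.fixture(scope="session")
def flavor_tax(taxonomies):
    return taxonomies[2]


@pytest.fixture(scope="session")
def scorer():
    return LexiconScorer()


def make_post(text, post_id="p1", user_id="u1", ts=1425168000):
    return Post(post_id, user_id, ts, text)


@pytest.fixture
def post_factory():
    return make_post
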