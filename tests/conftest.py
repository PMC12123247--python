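import pytest
from hypothesis import settings

from omopmap.embedding import HashedNgramEmbedder, build_index
from omopmap.fixtures import demo_collection

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def demo_col():
    """Ten-concept demonstration vocabulary (demographics + clinical findings)."""
    return demo_collection()


@pytest.fixture(scope="session")
def provider():
    return HashedNgramEmbedder(dimension=512, seed=42)


@pytest.fixture(scope="session")
def demo_index(demo_col, provider):
    return build_index(demo_col, provider)
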