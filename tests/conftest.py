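import pytest
from hypothesis import settings

from flicurate.model import ReferenceIndex

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")
from flicurate.simulate import FixtureSpec, make_query_set, make_reference


@pytest.fixture(scope="session")
def small_spec() -> FixtureSpec:
    return FixtureSpec(seed=7, n_genes=20)


@pytest.fixture(scope="session")
def small_reference(small_spec):
    return make_reference(small_spec)


@pytest.fixture(scope="session")
def small_reference_index(small_reference) -> ReferenceIndex:
    return small_reference.index()


@pytest.fixture(scope="session")
def small_query(small_spec, small_reference):
    return make_query_set(small_spec, small_reference)
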