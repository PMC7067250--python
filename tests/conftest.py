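import pytest

from flexnets.fixtures import FIXTURES


@pytest.fixture
def fx(request):
    """Indirect fixture: build a named example net fresh per test."""
    return FIXTURES[request.param]()


def make(name):
    return FIXTURES[name]()


@pytest.fixture
def fig2a():
    return make("fig2a")


@pytest.fixture
def fig3a():
    return make("fig3a")


@pytest.fixture
def fig6():
    return make("fig6")


@pytest.fixture
def fig8():
    return make("fig8")


@pytest.fixture
def fig10a():
    return make("fig10a")
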