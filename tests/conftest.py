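import pytest

from hfcea.params import paper_default_params


@pytest.fixture(scope="session")
def defaults():
    """Published base-case parameter set (shared, treat as read-only)."""
    return paper_default_params()


@pytest.fixture(scope="session")
def dapa_fit():
    from hfcea.model import MarkovCEA

    return MarkovCEA.paper_defaults(pair="dapa").fit()


@pytest.fixture(scope="session")
def empa_fit():
    from hfcea.model import MarkovCEA

    return MarkovCEA.paper_defaults(pair="empa").fit()
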