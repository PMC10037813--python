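import pytest

from caredyn import load_preset

POP = 1_000_000.0


@pytest.fixture(scope="session")
def table1():
    """Generic model-analysis parameter set (P = one million, g = h = 0)."""
    return load_preset("table1").params


@pytest.fixture(scope="session")
def table2_preset():
    """Case-study preset with illustrative engagement/progression rates."""
    return load_preset("table2", i=0.06, v=0.30)


@pytest.fixture(scope="session")
def P():
    return POP
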