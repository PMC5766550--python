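import numpy as np
import pytest

from predose.humanize import load_phantom
from predose.mird import icrp26_scheme, icrp60_scheme, load_reference_organ_doses


@pytest.fixture(scope="session")
def phantom():
    return load_phantom()


@pytest.fixture(scope="session")
def icrp60():
    return icrp60_scheme()


@pytest.fixture(scope="session")
def icrp26():
    return icrp26_scheme()


@pytest.fixture(scope="session")
def reference_doses():
    """Published organ dose-coefficient table (uSv/MBq), organ rows only."""
    df = load_reference_organ_doses()
    return df[df["kind"] == "organ"].set_index("organ")


@pytest.fixture(scope="session")
def reference_summaries():
    df = load_reference_organ_doses()
    return df[df["kind"] == "summary"].set_index("organ")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
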