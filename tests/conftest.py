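import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from labmotif import (
    ELECTRODE_LABELS,
    LabeledDigraph,
    NetworkSample,
    validate_network,
)


@pytest.fixture(scope="session")
def electrodes():
    return ELECTRODE_LABELS


@pytest.fixture
def empty_nine(electrodes):
    return validate_network(electrodes, np.zeros((9, 9), dtype=int))


@pytest.fixture
def complete_nine(electrodes):
    mat = np.ones((9, 9), dtype=int) - np.eye(9, dtype=int)
    return validate_network(electrodes, mat)


@pytest.fixture
def abc_path():
    """a -> b -> c on exactly three vertices."""
    return LabeledDigraph(("a", "b", "c"), [("a", "b"), ("b", "c")])


@pytest.fixture
def complete_sample(complete_nine):
    return NetworkSample([complete_nine] * 16)
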