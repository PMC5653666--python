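import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ampindel.align import AlignmentScoring
from ampindel.reference import build_index, window_of
from ampindel.simulate import demo_reference


@pytest.fixture(scope="session")
def reference():
    return demo_reference()


@pytest.fixture(scope="session")
def index(reference):
    return build_index(reference)


@pytest.fixture(scope="session")
def window(reference):
    return window_of(reference)


@pytest.fixture(scope="session")
def scoring():
    return AlignmentScoring()


@pytest.fixture()
def rng():
    return np.random.default_rng(20259)


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
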