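import warnings

import numpy as np
import pytest

from mopatlas import synth
from mopatlas.codebook import build_codebook

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def codebook22():
    """The study's code parameters: 22 bits, weight 4, distance 4, 242+10 entries."""
    return build_codebook(22, 4, 4, 242, 10, seed=1)


@pytest.fixture(scope="session")
def atlas6k():
    """A mid-size default-condition atlas shared by read-only tests."""
    return synth.generate_atlas(n_cells=6000, seed=7)


@pytest.fixture(scope="session")
def channel_groups(atlas6k):
    cols = list(atlas6k.sequential.columns)
    return {"650": cols[:8], "750": cols[8:]}
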