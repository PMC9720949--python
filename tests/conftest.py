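import numpy as np
import pytest

import polyscfv as p
from polyscfv.annotation import VH_TEMPLATE, VL_TEMPLATE
from polyscfv.dataset import DEFAULT_LINKER


@pytest.fixture(scope="session")
def synthetic_batch():
    """100 seeded synthetic records with ground truth (no structures:
    annotation-level tests don't need them)."""
    return p.generate_synthetic(100, seed=0, with_structures=False)


@pytest.fixture(scope="session")
def synthetic_structured():
    """A smaller batch with pseudo-structures for featurization tests."""
    return p.generate_synthetic(40, seed=1, with_structures=True)


@pytest.fixture(scope="session")
def template_scfv():
    """The consensus templates joined by the default linker."""
    seq = VH_TEMPLATE.sequence + DEFAULT_LINKER + VL_TEMPLATE.sequence
    return p.ScFvRecord(id="template", sequence=seq, label=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
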