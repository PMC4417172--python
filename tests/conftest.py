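import numpy as np
import pytest

from pausekit import GeneModel, KineticParams


@pytest.fixture
def plus_gene():
    return GeneModel("gplus", "chr1", "+", 100_000)


@pytest.fixture
def minus_gene():
    return GeneModel("gminus", "chr1", "-", 200_000)


@pytest.fixture
def default_params():
    return KineticParams(seed=11)


@pytest.fixture
def point_params():
    """Degenerate distributions: every read starts at the TSS, pauses at +34."""
    return KineticParams(
        pause_offset_dist={34: 1.0}, tss_jitter_dist={0: 1.0}, seed=7
    )


@pytest.fixture
def rng():
    return np.random.default_rng(123)
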