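import numpy as np
import pytest

from orthocis.motifs import default_motif_library


@pytest.fixture(scope="session")
def library():
    return default_motif_library()


@pytest.fixture()
def rng():
    return np.random.default_rng(20120867)


@pytest.fixture(scope="session", autouse=True)
def warm_aligner():
    # trigger the one-off numba compilation outside individual test timings
    from orthocis.align import align_pair

    align_pair("ACGT", "ACGT")
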