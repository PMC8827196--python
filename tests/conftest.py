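import numpy as np
import pytest

from deltadepth import DepthProfile


@pytest.fixture
def constant_profile():
    return DepthProfile("chr1", np.full(6, 2, dtype=np.int64), sample_id="wt")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
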