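import numpy as np
import pytest

from looprule.loop_finder import EndpointPair, LoopPath


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_loop_path(vertices, label="q-r", lcg_id="lcg0"):
    """Wrap a raw vertex array as a feasible LoopPath for measurement tests."""
    v = np.asarray(vertices, dtype=float)
    pair = EndpointPair(label=label, e1=v[0], e2=v[-1])
    return LoopPath(pair=pair, lcg_id=lcg_id, vertices=v, attach_lengths=(0.0, 0.0), feasible=True)
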