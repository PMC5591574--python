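import numpy as np
import pytest
from hypothesis import settings

import eyescript as es

settings.register_profile("suite", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def templates():
    return es.builtin_templates()


@pytest.fixture(scope="session")
def ttraces():
    return es.template_traces()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_epochs(templates):
    """One noiseless simulated epoch per digit, plus its reconstruction."""
    out = {}
    for digit in range(10):
        ep = es.simulate_epoch(templates[digit], es.clean_config(), seed=1)
        out[digit] = (ep, es.reconstruct(ep.recording))
    return out


def random_trace(rng, n, normalized=True):
    pts = rng.random((n, 2))
    return es.EyeTrace(pts, normalized=normalized)
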