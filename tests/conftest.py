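import numpy as np
import pandas as pd
import pytest


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


def make_events(n=1000, acceptor=None, fret=None, seed=0):
    """Minimal event table with all channels inside the default gates."""
    r = np.random.default_rng(seed)
    if acceptor is None:
        acceptor = 10.0 ** r.normal(2.5, 0.7, n)
    acceptor = np.asarray(acceptor, float)
    n = len(acceptor)
    if fret is None:
        fret = r.normal(0, 0.05, n) * acceptor
    return pd.DataFrame(
        {
            "fsc_a": np.full(n, 5e4),
            "fsc_h": np.full(n, 5e4),
            "fsc_w": np.full(n, 70.0),
            "ssc_a": np.full(n, 3e4),
            "donor": 0.6 * acceptor,
            "autofluor": np.full(n, 10.0),
            "acceptor": acceptor,
            "fret": np.asarray(fret, float),
        }
    )
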