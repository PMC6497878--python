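"""Shared fixtures: small simulated ensembles reused across unit tests."""

import numpy as np
import pytest

import hicomm
from hicomm import community as comm
from hicomm import contacts as cm
from hicomm import pipeline as pipe


@pytest.fixture(scope="session")
def fg_small():
    """Three small fractal globules with annealed-snapshot contact maps."""
    confs, maps = [], []
    for seed in (11, 12, 13):
        conf, cmap = pipe.simulate_fg_map(256, seed=seed, n_snapshots=30)
        confs.append(conf)
        maps.append(cmap)
    return {"confs": confs, "maps": maps, "n_snapshots": 30}


@pytest.fixture(scope="session")
def fg_small_balanced(fg_small):
    return [cm.kr_balance(m) for m in fg_small["maps"]]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_symmetric_map(rng, n, masked=()):
    """Dense positive symmetric test matrix with optional masked bins."""
    a = rng.random((n, n)) + 0.1
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 0.0)
    mask = np.zeros(n, dtype=bool)
    for i in masked:
        mask[i] = True
        a[i, :] = 0.0
        a[:, i] = 0.0
    return cm.ContactMap(a, mask=mask)
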