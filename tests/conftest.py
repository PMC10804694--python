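import numpy as np
import pytest

from fwtract.synthetic import (
    BiTensorGroundTruth,
    eigenvalues_for_fa,
    make_gradient_scheme,
)


@pytest.fixture(scope="session")
def scheme64():
    """The study acquisition: one b0 plus 64 directions at b = 1000 s/mm^2."""
    return make_gradient_scheme(64, b=1000.0, seed=1)


@pytest.fixture(scope="session")
def scheme32():
    return make_gradient_scheme(32, b=1000.0, seed=2)


def flat_truth(f, eigenvalues, orientation=None, s0=400.0):
    """Ground truth laid out as an (n, 1, 1) pencil of voxels."""
    f = np.atleast_1d(np.asarray(f, float))
    n = len(f)
    ev = np.broadcast_to(np.asarray(eigenvalues, float), (n, 3)).copy()
    if orientation is None:
        orientation = np.tile([1.0, 0.0, 0.0], (n, 1))
    ori = np.broadcast_to(np.asarray(orientation, float), (n, 3)).copy()
    return BiTensorGroundTruth(
        f.reshape(n, 1, 1),
        ev.reshape(n, 1, 1, 3),
        ori.reshape(n, 1, 1, 3),
        np.full((n, 1, 1), float(s0)),
    )


@pytest.fixture(scope="session")
def strata_phantom(scheme64):
    """The recovery phantom: every (f, tissue-FA) stratum, interleaved."""
    rng = np.random.default_rng(12345)
    f_levels = np.round(np.arange(0.0, 0.61, 0.1), 2)
    fa_levels = (0.2, 0.5, 0.7)
    per = 160
    f_all, ev_all = [], []
    for fv in f_levels:
        for fa in fa_levels:
            f_all += [fv] * per
            ev_all += [eigenvalues_for_fa(fa, 0.7e-3)] * per
    f_all = np.array(f_all)
    ev_all = np.array(ev_all)
    ori = rng.standard_normal((len(f_all), 3))
    truth = flat_truth(f_all, ev_all, ori)
    return truth, f_levels, fa_levels, per
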