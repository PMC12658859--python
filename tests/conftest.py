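import numpy as np
import pytest

import scquant as sq


@pytest.fixture
def sc_acq():
    return sq.SC_ACQUISITION


@pytest.fixture
def cytof_acq():
    return sq.CYTOF_ACQUISITION


@pytest.fixture
def sc_calib():
    return sq.default_sc_calibration()


@pytest.fixture
def cytof_calibs():
    return sq.default_cytof_calibrations()


def brute_force_detect(values, n_sigma=3.0, max_iter=100, ddof=1):
    """Independent reference of the iterative mean + n*sigma event loop.

    Deliberately naive (python lists, recompute everything each pass); used
    as the oracle the vectorised implementation must match exactly.
    """
    values = [float(v) for v in values]
    flagged = [False] * len(values)
    for _ in range(max_iter):
        background = [v for v, f in zip(values, flagged) if not f]
        if not background:
            raise ValueError("no background")
        m = sum(background) / len(background)
        if len(background) > 1:
            var = sum((v - m) ** 2 for v in background) / (len(background) - ddof)
            s = var ** 0.5
        else:
            s = 0.0
        thr = m + n_sigma * s
        new = [i for i, (v, f) in enumerate(zip(values, flagged)) if not f and v > thr]
        if not new:
            return sorted(i for i, f in enumerate(flagged) if f), thr, m, s
        for i in new:
            flagged[i] = True
    raise ValueError("no convergence")


@pytest.fixture
def detect_oracle():
    return brute_force_detect


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
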