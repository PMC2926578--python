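"""Shared fixtures: the simulated signal pair and its IC series.

The heavier chirp-derived objects are session-scoped so the estimator
runs once per configuration for the whole suite.
"""

from __future__ import annotations

import numpy as np
import pytest

import gammasync as gs
from gammasync.preprocess import GammaSignal, find_half_cycles
from gammasync.ic import WindowSpec, ic_series
from gammasync.simulate import variable_window_increment


@pytest.fixture(scope="session")
def chirp():
    return gs.gen_chirp_pair()


@pytest.fixture(scope="session")
def chirp_signals(chirp):
    x = GammaSignal(values=chirp.x, rate=chirp.rate, label="X")
    y = GammaSignal(values=chirp.y, rate=chirp.rate, label="Y")
    return x, y


@pytest.fixture(scope="session")
def chirp_partition(chirp_signals):
    return find_half_cycles(chirp_signals[0], method="zero_cross")


@pytest.fixture(scope="session")
def chirp_ic(chirp_signals, chirp_partition):
    """Variable-window IC series of the pair for w in {3, 6, 18}, base X."""
    x, y = chirp_signals
    out = {}
    for w in (3, 6, 18):
        spec = WindowSpec(w=w, m=variable_window_increment(w))
        out[w] = ic_series(x, [y], chirp_partition, spec)
    return out


@pytest.fixture(scope="session")
def chirp_freqs(chirp):
    fx = gs.observed_frequency(chirp.x, chirp.rate)
    fy = gs.observed_frequency(chirp.y, chirp.rate)
    nd = gs.normalized_freq_diff(fx, fy)
    return fx, fy, nd


def nearest_values(query_t: np.ndarray, series_t: np.ndarray, values: np.ndarray):
    """Value of a time series at the sample nearest each query time."""
    query_t = np.atleast_1d(query_t)
    pos = np.clip(np.searchsorted(series_t, query_t), 1, series_t.size - 1)
    pick = np.where(
        np.abs(series_t[pos] - query_t) < np.abs(series_t[pos - 1] - query_t),
        pos,
        pos - 1,
    )
    return values[pick]
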