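"""Shared fixtures for the hdmea test suite."""

from __future__ import annotations

import numpy as np
import pytest

from hdmea.grid import Recording, make_grid


@pytest.fixture
def grid5():
    return make_grid(5, 5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quiet_recording(grid5):
    """A 5x5 recording of pure Gaussian noise (sigma = 2 uV) at 5 kHz."""
    g = np.random.default_rng(7)
    data = g.normal(0.0, 2.0, size=(grid5.n_electrodes, 5000)).astype(np.float32)
    return Recording(grid=grid5, sampling_rate=5000.0, data=data)


def brute_force_sync_count(ref: np.ndarray, target: np.ndarray, window: float) -> int:
    """Independent O(n*m) oracle for synchronized-spike counting.

    A target spike u is synchronized with a reference spike t when
    t < u <= t + window; counts are summed over reference spikes, matching
    the package's per-reference-window convention.
    """
    n = 0
    for t in ref:
        for u in target:
            if t < u <= t + window:
                n += 1
    return n
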