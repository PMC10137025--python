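"""Shared fixtures: small deterministic instances of every domain object."""

import numpy as np
import pytest

from dfcp import (
    DfcsMatrix,
    FcMatrix,
    RoiTimeSeries,
    Wqcp,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_ts(rng):
    """A 30-timepoint, 5-ROI series with TR 2 s."""
    return RoiTimeSeries(
        values=rng.standard_normal((30, 5)),
        tr_seconds=2.0,
        subject_id="s1",
        group="case",
    )


@pytest.fixture
def random_fc(rng):
    """A valid random 6x6 static FC matrix."""
    a = rng.uniform(-1, 1, size=(6, 6))
    sym = (a + a.T) / 2
    np.fill_diagonal(sym, 0.0)
    return FcMatrix(values=sym, kind="static")


def make_dfcs(values, subject_id="s1", window_seconds=24.0, window_samples=12):
    return DfcsMatrix(
        values=np.asarray(values, dtype=float),
        window_length_seconds=window_seconds,
        window_length_samples=window_samples,
        step_samples=1,
        subject_id=subject_id,
    )


@pytest.fixture
def piecewise_dfcs(rng):
    """A planted three-level piecewise-constant dFCS matrix (N=6, W=30).

    Level shifts after windows 9 and 19; jump size 3 against noise sd 0.05
    (signal-to-noise well above 10).
    """
    n, w = 6, 30
    base = rng.uniform(1.0, 2.0, size=n)
    levels = [base, base + 3.0, base - 0.5]
    cols = np.empty((n, w))
    for t in range(w):
        level = 0 if t < 10 else (1 if t < 20 else 2)
        cols[:, t] = levels[level] + 0.05 * rng.standard_normal(n)
    return make_dfcs(np.clip(cols, 0, n - 1))


def random_wqcps(rng, n, dim, centers=None, spread=1.0):
    """WQCP cloud around optional centers; returns (wqcps, labels)."""
    if centers is None:
        centers = [np.zeros(dim)]
    labels = rng.integers(0, len(centers), size=n)
    wqcps = [
        Wqcp(
            values=np.asarray(centers[k]) + spread * rng.standard_normal(dim),
            window_span=(i, i + 1),
            subject_id=f"s{i}",
        )
        for i, k in enumerate(labels)
    ]
    return wqcps, labels
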