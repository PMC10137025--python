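"""Static and sliding-window functional connectivity.

Static FC is the Pearson correlation of each ROI pair over the full scan
(diagonal fixed at 0). Static strength sums each ROI's positive (default)
or absolute correlations. Dynamic FC slides a window of fixed length (given
in seconds, converted per subject with its TR) along the scan with step 1;
per window, the dynamic connectivity strength of ROI i is the sum of
absolute correlations to all other ROIs, and stacking these per-window
strength vectors as columns yields the N x W dFCS matrix.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np

from .data_model import (
    ConfigurationError,
    DfcpWarning,
    DfcsMatrix,
    FcMatrix,
    RoiTimeSeries,
    ShapeError,
    SfcStrengthVector,
)

__all__ = [
    "static_fc",
    "sfc_strength",
    "window_samples",
    "sliding_dfc",
    "dfcs_matrix",
    "dfcs_from_timeseries",
]


def _pearson_matrix(block: np.ndarray, kind: str) -> FcMatrix:
    """Pearson correlation of the columns of ``block``, zero diagonal.

    Zero-variance columns get zero correlations (with a warning) instead of
    propagating NaN, keeping strength sums bounded.
    """
    std = block.std(axis=0)
    degenerate = std == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance ROI column(s); "
            "their correlations are set to 0",
            DfcpWarning,
            stacklevel=3,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(block, rowvar=False)
    corr = np.asarray(corr, dtype=float)
    corr[~np.isfinite(corr)] = 0.0
    if degenerate.any():
        corr[degenerate, :] = 0.0
        corr[:, degenerate] = 0.0
    np.clip(corr, -1.0, 1.0, out=corr)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 0.0)
    return FcMatrix(values=corr, kind=kind)


def static_fc(ts: RoiTimeSeries) -> FcMatrix:
    """Pearson correlation matrix over all T time points, diagonal 0."""
    return _pearson_matrix(ts.values, kind="static")


def sfc_strength(fc: FcMatrix, mode: str = "positive_sum") -> SfcStrengthVector:
    """Per-ROI strength: sum of positive (default) or absolute correlations."""
    if mode == "positive_sum":
        values = np.maximum(fc.values, 0.0).sum(axis=1)
    elif mode == "absolute_sum":
        values = np.abs(fc.values).sum(axis=1)
    else:
        raise ValueError(f"unknown strength mode {mode!r}")
    return SfcStrengthVector(values=values, mode=mode)


def window_samples(window_seconds: float, tr_seconds: float) -> int:
    """Convert a window length in seconds to samples: round(w/TR), minimum 2.

    Expressing the window in seconds lets cohorts scanned at different TRs
    share the same nominal window.
    """
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    if window_seconds < 2 * tr_seconds:
        raise ConfigurationError(
            f"window of {window_seconds}s spans fewer than 2 samples at TR {tr_seconds}s"
        )
    return max(2, int(round(window_seconds / tr_seconds)))


def sliding_dfc(ts: RoiTimeSeries, w: int, step: int = 1) -> list[FcMatrix]:
    """Windowed Pearson FC: one matrix per window of ``w`` samples, stride ``step``.

    Window t covers samples ``[t*step, t*step + w)``; there are
    ``floor((T - w)/step) + 1`` windows.
    """
    T = ts.n_timepoints
    if not (2 <= w <= T):
        raise ConfigurationError(f"window of {w} samples invalid for T={T}")
    if step < 1:
        raise ValueError("step must be >= 1")
    n_windows = (T - w) // step + 1
    return [
        _pearson_matrix(ts.values[t * step : t * step + w, :], kind="windowed")
        for t in range(n_windows)
    ]


def dfcs_matrix(
    windows: Sequence[FcMatrix],
    window_length_seconds: float = float("nan"),
    window_length_samples: int | None = None,
    step_samples: int = 1,
    subject_id: str = "",
) -> DfcsMatrix:
    """Stack per-window absolute-sum strength vectors into the N x W dFCS matrix."""
    if not windows:
        raise ShapeError("need at least one window")
    n = windows[0].n_rois
    cols = []
    for fc in windows:
        if fc.n_rois != n:
            raise ShapeError(f"inconsistent ROI counts: {fc.n_rois} vs {n}")
        cols.append(np.abs(fc.values).sum(axis=1))
    return DfcsMatrix(
        values=np.column_stack(cols),
        window_length_seconds=window_length_seconds,
        window_length_samples=window_length_samples if window_length_samples else 2,
        step_samples=step_samples,
        subject_id=subject_id,
    )


def dfcs_from_timeseries(
    ts: RoiTimeSeries, window_seconds: float, step: int = 1
) -> DfcsMatrix:
    """End-to-end dFCS: seconds-to-samples conversion, sliding FC, strength stack."""
    w = window_samples(window_seconds, ts.tr_seconds)
    if w > ts.n_timepoints:
        raise ConfigurationError(
            f"window of {w} samples exceeds scan length T={ts.n_timepoints}"
        )
    windows = sliding_dfc(ts, w, step)
    return dfcs_matrix(
        windows,
        window_length_seconds=window_seconds,
        window_length_samples=w,
        step_samples=step,
        subject_id=ts.subject_id,
    )
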