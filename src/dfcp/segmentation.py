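"""Automatic quasi-stable segmentation of a dFCS matrix along time.

Adjacent time slices of a dFCS matrix tend to be similar while a state
switch produces a jump, so a boundary is declared after window t whenever
the Euclidean distance between columns t and t+1 exceeds
``mean(d) + alpha * std(d)`` over all adjacent distances d. Segments
shorter than ``min_segment_windows`` are merged into the neighbour across
the weaker boundary. Each resulting segment is summarized by its
columnwise mean -- a whole-brain quasi-stable connectome pattern (WQCP).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import DfcsMatrix, ValidationError, Wqcp

__all__ = ["SegmentationParams", "adjacent_distances", "segment", "wqcps_from_segments", "extract_wqcps"]


@dataclass(frozen=True)
class SegmentationParams:
    """Threshold multiplier ``alpha`` (boundary at mean + alpha*std of the
    adjacent-distance series) and the minimum segment length in windows."""

    alpha: float = 1.0
    min_segment_windows: int = 2

    def __post_init__(self):
        if self.alpha < 0:
            raise ValidationError("alpha must be nonnegative")
        if self.min_segment_windows < 1:
            raise ValidationError("min_segment_windows must be >= 1")


def adjacent_distances(d: DfcsMatrix) -> np.ndarray:
    """Euclidean distance between consecutive time columns; length W-1."""
    v = d.values
    return np.linalg.norm(np.diff(v, axis=1), axis=0)


def segment(d: DfcsMatrix, p: SegmentationParams | None = None) -> list[tuple[int, int]]:
    """Partition window indices [0, W) into quasi-stable half-open spans.

    A boundary is placed after window t when the adjacent distance strictly
    exceeds mean + alpha*std (so a constant distance series yields a single
    span). Undersized segments are merged toward the neighbour whose shared
    boundary has the smaller distance; ties merge left.
    """
    p = p or SegmentationParams()
    W = d.n_windows
    if W <= max(1, p.min_segment_windows):
        return [(0, W)]

    dist = adjacent_distances(d)
    threshold = dist.mean() + p.alpha * dist.std()
    boundaries = [t + 1 for t in range(W - 1) if dist[t] > threshold]
    spans = _spans_from_boundaries(boundaries, W)

    # merge undersized segments, shortest (leftmost on ties) first
    while len(spans) > 1:
        lengths = [e - s for s, e in spans]
        idx = int(np.argmin(lengths))
        if lengths[idx] >= p.min_segment_windows:
            break
        start, end = spans[idx]
        left_d = dist[start - 1] if idx > 0 else np.inf
        right_d = dist[end - 1] if idx < len(spans) - 1 else np.inf
        if left_d <= right_d:  # ties merge left
            spans[idx - 1] = (spans[idx - 1][0], end)
        else:
            spans[idx + 1] = (start, spans[idx + 1][1])
        del spans[idx]
    return spans


def _spans_from_boundaries(boundaries: list[int], W: int) -> list[tuple[int, int]]:
    edges = [0] + boundaries + [W]
    return [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]


def wqcps_from_segments(d: DfcsMatrix, spans: list[tuple[int, int]]) -> list[Wqcp]:
    """Columnwise mean of the dFCS columns in each span."""
    out = []
    for start, end in spans:
        if not (0 <= start < end <= d.n_windows):
            raise ValidationError(f"span [{start}, {end}) invalid for W={d.n_windows}")
        out.append(
            Wqcp(
                values=d.values[:, start:end].mean(axis=1),
                window_span=(start, end),
                subject_id=d.subject_id,
            )
        )
    return out


def extract_wqcps(d: DfcsMatrix, p: SegmentationParams | None = None) -> list[Wqcp]:
    """Segment then average: the per-subject WQCP list."""
    return wqcps_from_segments(d, segment(d, p))
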