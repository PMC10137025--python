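"""Aggregation and statistical comparison of cross-validation runs.

Per-run confusion counts are reduced to metric summaries (mean, sample
standard deviation, 95% t-based confidence interval), approaches are
compared metric-by-metric with a two-sample t-test (pooled variance by
default), and the sensitivity of performance to the sliding-window length
is expressed as the Pearson correlation between the window lengths and the
per-window metric means.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classification import metrics
from .data_model import CvRunResult, ValidationError

__all__ = [
    "METRIC_NAMES",
    "run_metric_values",
    "aggregate",
    "compare_approaches",
    "window_correlation",
    "feature_intersection",
]

METRIC_NAMES = ("accuracy", "precision", "recall", "specificity", "f1")


def run_metric_values(runs: Sequence[CvRunResult], metric: str) -> np.ndarray:
    """The per-run values of one metric."""
    if metric not in METRIC_NAMES:
        raise ValidationError(f"unknown metric {metric!r}")
    return np.asarray([metrics(r)[metric] for r in runs], dtype=float)


def aggregate(runs: Sequence[CvRunResult]) -> pd.DataFrame:
    """Summarize runs: one row per metric with mean, std and 95% CI.

    The CI is mean +/- t(0.975, n-1) * std / sqrt(n); with a single run the
    CI is undefined and reported as NaN.
    """
    runs = list(runs)
    if not runs:
        raise ValidationError("cannot aggregate zero runs")
    rows = []
    n = len(runs)
    for metric in METRIC_NAMES:
        vals = run_metric_values(runs, metric)
        mean = float(vals.mean())
        if n >= 2:
            sd = float(vals.std(ddof=1))
            half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
            lo, hi = mean - half, mean + half
        else:
            sd, lo, hi = float("nan"), float("nan"), float("nan")
        rows.append(
            {"metric": metric, "mean": mean, "std": sd, "ci_low": lo, "ci_high": hi, "n": n}
        )
    return pd.DataFrame(rows).set_index("metric")


def compare_approaches(
    runs_a: Sequence[CvRunResult],
    runs_b: Sequence[CvRunResult],
    metric: str,
    equal_var: bool = True,
) -> dict:
    """Two-sample t-test on per-run metric values of two approaches.

    Pooled variance by default (Welch via ``equal_var=False``). When both
    samples are constant and equal the difference is exactly zero and p is
    reported as 1.
    """
    a = run_metric_values(runs_a, metric)
    b = run_metric_values(runs_b, metric)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both run sets must be nonempty")
    if a.std() == 0 and b.std() == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
        t = 0.0 if p == 1.0 else float("inf")
    else:
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return {
        "metric": metric,
        "t": float(t),
        "p": float(p),
        "significant": bool(p < 0.05),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
    }


def window_correlation(
    window_lengths: Sequence[float], metric_means: Sequence[float]
) -> float:
    """Pearson r between window lengths and per-window metric means.

    NaN (with no exception) when either vector has zero variance.
    """
    x = np.asarray(list(window_lengths), dtype=float)
    y = np.asarray(list(metric_means), dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValidationError("need equal-length vectors of length >= 3")
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def feature_intersection(selected_sets: Sequence[Sequence[int]]) -> set[int]:
    """Indices selected in every fold/repeat — the stable feature core."""
    sets = [set(int(i) for i in s) for s in selected_sets]
    if not sets:
        raise ValidationError("need at least one selected-feature set")
    out = sets[0]
    for s in sets[1:]:
        out = out & s
    return out
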