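"""Domain types and on-disk formats for the DFCP classification pipeline.

Every object that crosses a module boundary is defined here, together with
its invariants and its plain-text serialization:

* :class:`RoiTimeSeries` -- one subject's ROI-averaged resting-state series
  (T time points x N ROIs) with repetition time and group label.
* :class:`FcMatrix` -- an N x N functional-connectivity (Pearson) matrix.
* :class:`SfcStrengthVector` -- per-ROI static connectivity strength.
* :class:`DfcsMatrix` -- the N x W dynamic-connectivity-strength matrix over
  sliding windows.
* :class:`Wqcp` -- a whole-brain quasi-stable connectome pattern: the time
  average of dFCS columns over one quasi-stable segment.
* :class:`DfcpModel` -- the fitted dynamic-functional-connectome-pattern
  model (cluster centroids plus clustering metadata).
* :class:`FeatureVector` -- a subject's classification features.
* :class:`CvRunResult` / metric tables -- cross-validation bookkeeping.

Time series are stored time-major on disk (rows = time points); readers can
be told the transpose explicitly. Window and segment indices are 0-based,
half-open throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SCHEMA_VERSION = 1

GROUPS = ("case", "control")


class DfcpError(Exception):
    """Base class for all pipeline errors."""


class ValidationError(DfcpError):
    """A domain-type invariant is violated."""


class ParseError(DfcpError):
    """An on-disk artifact cannot be parsed."""


class MetadataError(DfcpError):
    """Required metadata (TR, group, orientation, ...) is missing or bad."""


class ShapeError(DfcpError):
    """Arrays with inconsistent dimensions were combined."""


class ConfigurationError(DfcpError):
    """A parameter combination is unusable (e.g. window longer than scan)."""


class LeakageError(DfcpError):
    """Test-subject data reached a fitting step."""


class DfcpWarning(UserWarning):
    """Base class for data-quality warnings (zero variance, empty subjects)."""


def _as_float_array(values, name: str, ndim: int) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != ndim:
        raise ValidationError(f"{name} must be {ndim}-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        bad = np.argwhere(~np.isfinite(arr))[0]
        raise ValidationError(f"{name} contains a non-finite value at index {tuple(bad)}")
    return arr


# ---------------------------------------------------------------------------
# Core domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RoiTimeSeries:
    """One subject's ROI-averaged time series.

    Parameters
    ----------
    values : ndarray, shape (T, N)
        Signal matrix, time-major. Units are arbitrary: every downstream
        statistic is a Pearson correlation and therefore invariant to
        per-ROI affine rescaling.
    tr_seconds : float
        Repetition time (sampling interval) in seconds.
    subject_id : str
    group : {"case", "control"}
        ``case`` is the patient (positive) class throughout.
    cohort : str
        Free-form cohort tag (e.g. scanner site).
    """

    values: np.ndarray
    tr_seconds: float
    subject_id: str
    group: str
    cohort: str = ""

    def __post_init__(self):
        arr = _as_float_array(self.values, "time series", 2)
        object.__setattr__(self, "values", arr)
        if arr.shape[0] < 2:
            raise ValidationError(f"need at least 2 time points, got {arr.shape[0]}")
        if arr.shape[1] < 2:
            raise ValidationError(f"need at least 2 ROIs, got {arr.shape[1]}")
        if not (np.isfinite(self.tr_seconds) and self.tr_seconds > 0):
            raise MetadataError(f"tr_seconds must be positive, got {self.tr_seconds}")
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}, got {self.group!r}")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class FcMatrix:
    """A functional-connectivity matrix: symmetric, zero diagonal, entries in [-1, 1]."""

    values: np.ndarray
    kind: str = "static"  # or "windowed"

    def __post_init__(self):
        arr = _as_float_array(self.values, "FC matrix", 2)
        object.__setattr__(self, "values", arr)
        n, m = arr.shape
        if n != m:
            raise ValidationError(f"FC matrix must be square, got {arr.shape}")
        if self.kind not in ("static", "windowed"):
            raise ValidationError(f"kind must be 'static' or 'windowed', got {self.kind!r}")
        if not np.allclose(arr, arr.T, atol=1e-10):
            raise ValidationError("FC matrix must be symmetric")
        if np.any(np.abs(np.diagonal(arr)) > 1e-12):
            raise ValidationError("FC matrix diagonal must be exactly 0")
        if np.any(np.abs(arr) > 1 + 1e-10):
            raise ValidationError("FC entries must lie in [-1, 1]")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class SfcStrengthVector:
    """Per-ROI static FC strength (sum of positive or absolute correlations)."""

    values: np.ndarray
    mode: str = "positive_sum"  # or "absolute_sum"

    def __post_init__(self):
        arr = _as_float_array(self.values, "strength vector", 1)
        object.__setattr__(self, "values", arr)
        if self.mode not in ("positive_sum", "absolute_sum"):
            raise ValidationError(f"unknown strength mode {self.mode!r}")
        n = arr.shape[0]
        if np.any(arr < -1e-10) or np.any(arr > n - 1 + 1e-8):
            raise ValidationError(f"strength values must lie in [0, {n - 1}]")


@dataclass(frozen=True)
class DfcsMatrix:
    """Dynamic functional connectivity strength: ROI x window matrix.

    Entry (i, t) is the sum over j != i of |corr_t(i, j)| for sliding
    window t, so every entry lies in [0, N-1].
    """

    values: np.ndarray  # (N, W)
    window_length_seconds: float
    window_length_samples: int
    step_samples: int = 1
    subject_id: str = ""

    def __post_init__(self):
        arr = _as_float_array(self.values, "dFCS matrix", 2)
        object.__setattr__(self, "values", arr)
        if self.window_length_samples < 2:
            raise ValidationError("window_length_samples must be >= 2")
        if self.step_samples < 1:
            raise ValidationError("step_samples must be >= 1")
        n = arr.shape[0]
        if np.any(arr < -1e-10) or np.any(arr > n - 1 + 1e-8):
            raise ValidationError(f"dFCS entries must lie in [0, {n - 1}]")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class Wqcp:
    """Whole-brain quasi-stable connectome pattern.

    The columnwise mean of a dFCS matrix over one quasi-stable segment
    ``[start, end)`` of window indices (half-open, 0-based).
    """

    values: np.ndarray  # (N,)
    window_span: tuple[int, int]
    subject_id: str = ""

    def __post_init__(self):
        arr = _as_float_array(self.values, "WQCP", 1)
        object.__setattr__(self, "values", arr)
        start, end = self.window_span
        if not (0 <= start < end):
            raise ValidationError(f"invalid window span [{start}, {end})")
        object.__setattr__(self, "window_span", (int(start), int(end)))


@dataclass(frozen=True)
class DfcpModel:
    """Fitted dynamic functional connectome patterns.

    ``centroids`` holds the K pattern vectors R_k as columns (N x K); each
    is the mean of its member WQCPs after twice-clustering. ``elbow_curve``
    records the within-cluster dispersion at each candidate K so the
    elbow choice can be audited.
    """

    centroids: np.ndarray  # (N, K)
    kmeans_k0: int
    linkage: str
    k_candidates: tuple[int, ...]
    elbow_curve: np.ndarray
    random_seed: int

    def __post_init__(self):
        arr = _as_float_array(self.centroids, "centroids", 2)
        object.__setattr__(self, "centroids", arr)
        object.__setattr__(self, "k_candidates", tuple(int(k) for k in self.k_candidates))
        object.__setattr__(self, "elbow_curve", np.asarray(self.elbow_curve, dtype=float))
        if arr.shape[1] < 1:
            raise ValidationError("model must have at least one centroid")
        if self.k_candidates and self.K not in self.k_candidates:
            raise ValidationError(
                f"K={self.K} not among candidate counts {self.k_candidates}"
            )

    @property
    def K(self) -> int:
        return self.centroids.shape[1]


@dataclass(frozen=True)
class FeatureVector:
    """A subject's classification features.

    ``ratios`` is the DFCP occupancy distribution (length K, sums to 1
    unless the subject has no WQCPs and was flagged), ``mean_betas`` the
    subject-mean least-squares coefficients onto the centroids (length K),
    and ``sfc_strength`` the optional per-ROI static strength block.
    """

    ratios: np.ndarray
    mean_betas: np.ndarray
    subject_id: str
    group: str
    sfc_strength: np.ndarray | None = None
    flagged: bool = False

    def __post_init__(self):
        r = _as_float_array(self.ratios, "ratios", 1)
        b = _as_float_array(self.mean_betas, "mean_betas", 1)
        object.__setattr__(self, "ratios", r)
        object.__setattr__(self, "mean_betas", b)
        if r.shape != b.shape:
            raise ShapeError("ratios and mean_betas must have equal length")
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}")
        if np.any(r < -1e-12):
            raise ValidationError("ratio features must be nonnegative")
        if not self.flagged and abs(r.sum() - 1.0) > 1e-8:
            raise ValidationError("ratio features must sum to 1")
        if self.sfc_strength is not None:
            s = _as_float_array(self.sfc_strength, "sfc_strength", 1)
            object.__setattr__(self, "sfc_strength", s)

    def concatenated(self, include_sfc: bool = True) -> np.ndarray:
        parts = [self.ratios, self.mean_betas]
        if include_sfc and self.sfc_strength is not None:
            parts = [self.sfc_strength] + parts
        return np.concatenate(parts)


@dataclass(frozen=True)
class CvRunResult:
    """Confusion counts and provenance for one (repeat, fold) evaluation."""

    tp: int
    fp: int
    tn: int
    fn: int
    repeat: int
    fold: int
    approach: str = ""
    selected_features: tuple[int, ...] = ()
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")
        object.__setattr__(
            self, "selected_features", tuple(int(i) for i in self.selected_features)
        )

    @property
    def n_test(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_roi_timeseries(
    path: str | Path,
    sidecar: str | Path | None = None,
    orientation: str | None = None,
) -> RoiTimeSeries:
    """Read a delimited numeric matrix plus its JSON sidecar.

    The matrix is time-major (rows = time points) unless ``orientation`` or
    the sidecar key ``orientation`` says ``"roi_major"``. A square matrix
    with no declared orientation is rejected as ambiguous.

    Raises
    ------
    ParseError
        Missing or non-numeric cells (the offending row/column is named).
    MetadataError
        Absent sidecar, TR, or undeclared orientation on a square matrix.
    ValidationError
        Fewer than 2 time points or ROIs.
    """
    path = Path(path)
    if sidecar is None:
        sidecar = path.with_suffix(".json")
    sidecar = Path(sidecar)
    if not sidecar.exists():
        raise MetadataError(f"sidecar not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("tr_seconds", "subject_id", "group"):
        if key not in meta:
            raise MetadataError(f"sidecar {sidecar} missing required key {key!r}")

    try:
        with open(path) as fh:
            first = fh.readline()
        sep = "\t" if "\t" in first else ("," if "," in first else r"\s+")
        frame = pd.read_csv(
            path, sep=sep, header=None, comment="#",
            float_precision="round_trip",
        )
    except OSError as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc
    except Exception as exc:  # malformed delimiter structure
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    values = frame.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        for j, col in enumerate(frame.columns):
            coerced = pd.to_numeric(frame[col], errors="coerce")
            bad = coerced.index[coerced.isna() & frame[col].notna()]
            if len(bad):
                raise ParseError(
                    f"{path}: non-numeric cell at row {bad[0]}, column {j}"
                )
        values = frame.apply(pd.to_numeric, errors="coerce").to_numpy()
    nan_idx = np.argwhere(np.isnan(values.astype(float)))
    if len(nan_idx):
        r, c = nan_idx[0]
        raise ParseError(f"{path}: missing/NaN cell at row {r}, column {c}")
    values = values.astype(float)

    orientation = orientation or meta.get("orientation")
    if values.shape[0] == values.shape[1] and orientation is None:
        raise MetadataError(
            f"{path}: square matrix is ambiguous; declare orientation "
            "('time_major' or 'roi_major')"
        )
    if orientation not in (None, "time_major", "roi_major"):
        raise MetadataError(f"unknown orientation {orientation!r}")
    if orientation == "roi_major":
        values = values.T

    return RoiTimeSeries(
        values=values,
        tr_seconds=float(meta["tr_seconds"]),
        subject_id=str(meta["subject_id"]),
        group=str(meta["group"]),
        cohort=str(meta.get("cohort", "")),
    )


def write_roi_timeseries(ts: RoiTimeSeries, path: str | Path) -> Path:
    """Write a time-major TSV plus JSON sidecar; inverse of the reader."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, ts.values, delimiter="\t", fmt="%.17g")
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "tr_seconds": ts.tr_seconds,
                "subject_id": ts.subject_id,
                "group": ts.group,
                "cohort": ts.cohort,
                "orientation": "time_major",
            },
            indent=2,
        )
    )
    return path


def write_dfcs(d: DfcsMatrix, path: str | Path) -> Path:
    """Write a dFCS matrix as TSV (rows = ROIs) with a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, d.values, delimiter="\t", fmt="%.17g")
    path.with_suffix(".json").write_text(
        json.dumps(
            {
                "window_length_seconds": d.window_length_seconds,
                "window_length_samples": d.window_length_samples,
                "step_samples": d.step_samples,
                "subject_id": d.subject_id,
            },
            indent=2,
        )
    )
    return path


def read_dfcs(path: str | Path) -> DfcsMatrix:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    values = np.loadtxt(path, delimiter="\t", ndmin=2)
    return DfcsMatrix(
        values=values,
        window_length_seconds=float(meta["window_length_seconds"]),
        window_length_samples=int(meta["window_length_samples"]),
        step_samples=int(meta["step_samples"]),
        subject_id=str(meta.get("subject_id", "")),
    )


def write_wqcps(wqcps: Sequence[Wqcp], path: str | Path) -> Path:
    """One row per WQCP: subject_id, start, end, then the N values."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for w in wqcps:
        rows.append(
            {"subject_id": w.subject_id, "start": w.window_span[0], "end": w.window_span[1]}
            | {f"v{i}": x for i, x in enumerate(w.values)}
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def read_wqcps(path: str | Path) -> list[Wqcp]:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    value_cols = [c for c in frame.columns if c.startswith("v")]
    return [
        Wqcp(
            values=row[value_cols].to_numpy(dtype=float),
            window_span=(int(row["start"]), int(row["end"])),
            subject_id=str(row["subject_id"]),
        )
        for _, row in frame.iterrows()
    ]


def write_features(vectors: Iterable[FeatureVector], path: str | Path) -> Path:
    """Write feature vectors as TSV: ratio_1..K, mbeta_1..K, [sfcs_1..N], group.

    All vectors must share dimensionality and the presence/absence of the
    static-strength block; read-back reproduces values exactly.
    """
    vectors = list(vectors)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if not vectors:
        path.write_text("subject_id\tgroup\n")
        return path
    K = len(vectors[0].ratios)
    has_sfc = vectors[0].sfc_strength is not None
    n_sfc = len(vectors[0].sfc_strength) if has_sfc else 0
    rows = []
    for v in vectors:
        if len(v.ratios) != K or (v.sfc_strength is not None) != has_sfc or (
            has_sfc and len(v.sfc_strength) != n_sfc
        ):
            raise ShapeError("feature vectors have mixed dimensionality")
        row = {"subject_id": v.subject_id, "group": v.group}
        row.update({f"ratio_{k + 1}": v.ratios[k] for k in range(K)})
        row.update({f"mbeta_{k + 1}": v.mean_betas[k] for k in range(K)})
        if has_sfc:
            row.update({f"sfcs_{i + 1}": v.sfc_strength[i] for i in range(n_sfc)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def read_features(path: str | Path) -> list[FeatureVector]:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if frame.empty:
        return []
    ratio_cols = sorted(
        (c for c in frame.columns if c.startswith("ratio_")),
        key=lambda c: int(c.split("_")[1]),
    )
    beta_cols = sorted(
        (c for c in frame.columns if c.startswith("mbeta_")),
        key=lambda c: int(c.split("_")[1]),
    )
    sfc_cols = sorted(
        (c for c in frame.columns if c.startswith("sfcs_")),
        key=lambda c: int(c.split("_")[1]),
    )
    out = []
    for _, row in frame.iterrows():
        ratios = row[ratio_cols].to_numpy(dtype=float)
        out.append(
            FeatureVector(
                ratios=ratios,
                mean_betas=row[beta_cols].to_numpy(dtype=float),
                sfc_strength=row[sfc_cols].to_numpy(dtype=float) if sfc_cols else None,
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                flagged=bool(abs(ratios.sum() - 1.0) > 1e-8),
            )
        )
    return out


def save_model(model: DfcpModel, path: str | Path) -> Path:
    """Serialize a DfcpModel as a JSON bundle with schema version and seed."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(
        json.dumps(
            {
                "schema_version": SCHEMA_VERSION,
                "centroids": model.centroids.tolist(),
                "kmeans_k0": model.kmeans_k0,
                "linkage": model.linkage,
                "k_candidates": list(model.k_candidates),
                "elbow_curve": model.elbow_curve.tolist(),
                "random_seed": model.random_seed,
            }
        )
    )
    return path


def load_model(path: str | Path) -> DfcpModel:
    data = json.loads(Path(path).read_text())
    if data.get("schema_version") != SCHEMA_VERSION:
        raise MetadataError(
            f"unsupported model schema version {data.get('schema_version')!r}"
        )
    return DfcpModel(
        centroids=np.asarray(data["centroids"], dtype=float),
        kmeans_k0=int(data["kmeans_k0"]),
        linkage=str(data["linkage"]),
        k_candidates=tuple(data["k_candidates"]),
        elbow_curve=np.asarray(data["elbow_curve"], dtype=float),
        random_seed=int(data["random_seed"]),
    )


def read_manifest(path: str | Path) -> list[RoiTimeSeries]:
    """Read a cohort manifest (TSV with a ``path`` column of series files).

    Paths are resolved relative to the manifest's directory.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t")
    if "path" not in frame.columns:
        raise MetadataError(f"manifest {path} lacks a 'path' column")
    return [read_roi_timeseries(path.parent / p) for p in frame["path"]]
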