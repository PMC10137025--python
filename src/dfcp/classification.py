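"""SVM-RFE feature selection, SVM training, and the repeated-CV protocol.

The evaluation protocol is repeated stratified 5-fold cross-validation
(default 20 repeats, i.e. 100 train/test runs per approach). Inside every
fold, strictly on the training split: the DFCP model is clustered from the
training subjects' WQCPs, features are z-scored with training statistics,
SVM-RFE ranks features by backward elimination of the smallest squared
linear-SVM weights, the retained subset size is the ranking prefix with the
best inner-CV accuracy, and the final SVM's C (and gamma, for the RBF
kernel) are tuned by an inner stratified grid search. Test subjects touch
nothing but the frozen transform/predict path; a leakage guard raises if a
test subject's WQCPs ever reach the clustering step.

Three feature approaches are supported: ``sfc`` (per-ROI static strength,
N features), ``dfcp`` (occupancy ratios + mean betas, 2K features), and
``combined`` (N + 2K features).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .connectivity import dfcs_from_timeseries, sfc_strength, static_fc
from .data_model import (
    CvRunResult,
    DfcpWarning,
    LeakageError,
    RoiTimeSeries,
    ShapeError,
    ValidationError,
)
from .patterns import ClusteringParams, dfcp_features, twice_cluster
from .segmentation import SegmentationParams, extract_wqcps

__all__ = [
    "ProtocolParams",
    "APPROACHES",
    "stratified_folds",
    "svm_rfe",
    "train_svm",
    "evaluate_fold",
    "metrics",
    "run_protocol",
]

APPROACHES = ("sfc", "dfcp", "combined")

_DEFAULT_C_GRID = tuple(2.0 ** e for e in range(-5, 6))
_DEFAULT_GAMMA_GRID = tuple(2.0 ** e for e in range(-7, 2))


@dataclass(frozen=True)
class ProtocolParams:
    """Cross-validation and model-tuning parameters.

    Defaults follow the study protocol: 5 outer folds, 20 repeats (100
    runs), 5 inner folds, elimination step 1, RBF kernel with log-2 grids
    C in 2^-5..2^5 and gamma in 2^-7..2^1 (a linear kernel tunes C only).
    ``rfe_select`` chooses the subset size by inner CV (``"inner_cv"``) or
    fixes it (an integer).
    """

    outer_folds: int = 5
    repeats: int = 20
    inner_folds: int = 5
    rfe_step: int = 1
    rfe_select: int | str = "inner_cv"
    kernel: str = "rbf"
    C_grid: tuple[float, ...] = _DEFAULT_C_GRID
    gamma_grid: tuple[float, ...] = _DEFAULT_GAMMA_GRID
    sfc_mode: str = "positive_sum"
    seed: int = 0

    def __post_init__(self):
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValidationError("folds must be >= 2")
        if self.kernel not in ("linear", "rbf"):
            raise ValidationError("kernel must be 'linear' or 'rbf'")
        if not self.C_grid or not all(c > 0 for c in self.C_grid):
            raise ValidationError("C_grid must be nonempty and positive")
        if self.kernel == "rbf" and (
            not self.gamma_grid or not all(g > 0 for g in self.gamma_grid)
        ):
            raise ValidationError("gamma_grid must be nonempty and positive")
        if self.rfe_step < 1:
            raise ValidationError("rfe_step must be >= 1")


def stratified_folds(groups: Sequence[str], k: int, seed: int) -> np.ndarray:
    """Assign subjects to k folds, balanced per group (sizes differ by <= 1).

    Deterministic for a given seed. ``groups`` is the per-subject label
    sequence; the return value is a fold index per subject.
    """
    groups = np.asarray(list(groups))
    for g in np.unique(groups):
        if (groups == g).sum() < k:
            raise ValidationError(f"group {g!r} has fewer than {k} subjects")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(groups), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(groups)), groups)):
        assignment[test_idx] = fold
    return assignment


def _inner_cv_accuracy(clf, X: np.ndarray, y: np.ndarray, n_folds: int, seed: int) -> float:
    """Mean stratified-CV accuracy of ``clf`` (cloned per fold) on (X, y)."""
    n_folds = min(n_folds, int(np.bincount(y).min()))
    if n_folds < 2:
        return float("nan")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    accs = []
    for train_idx, test_idx in skf.split(X, y):
        m = clone(clf).fit(X[train_idx], y[train_idx])
        accs.append(float(np.mean(m.predict(X[test_idx]) == y[test_idx])))
    return float(np.mean(accs))


def svm_rfe(
    X: np.ndarray,
    y: np.ndarray,
    rfe_step: int = 1,
    select: int | str = "inner_cv",
    inner_folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Rank features by linear-SVM backward elimination and pick a subset.

    Each round fits a linear SVM on the surviving features and drops the
    ``rfe_step`` features with the smallest squared weights. Returns
    ``(ranking, selected)``: ``ranking`` lists feature indices best-first
    (reverse elimination order), ``selected`` is the retained prefix —
    either the prefix size with the best inner-CV accuracy (ties: smaller)
    or a fixed size when ``select`` is an integer.

    ``X`` is assumed standardized by the caller with training statistics.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    if p < 1:
        raise ValidationError("need at least one feature")
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes must be present")
    constant = X.std(axis=0) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature column(s) entered RFE",
            DfcpWarning,
            stacklevel=2,
        )

    remaining = list(range(p))
    eliminated: list[int] = []
    while len(remaining) > 1:
        svc = SVC(kernel="linear", C=C).fit(X[:, remaining], y)
        w2 = (svc.coef_**2).sum(axis=0)
        n_drop = min(rfe_step, len(remaining) - 1)
        drop_order = np.argsort(w2, kind="stable")[:n_drop]
        # smallest weights eliminated first within the round
        for local in sorted(drop_order, key=lambda i: (w2[i], remaining[i])):
            eliminated.append(remaining[local])
        remaining = [f for f in remaining if f not in set(eliminated)]
    ranking = np.asarray(remaining + eliminated[::-1], dtype=int)

    if isinstance(select, int):
        size = max(1, min(select, p))
    else:
        best_acc, size = -np.inf, 1
        for s in range(1, p + 1):
            acc = _inner_cv_accuracy(
                SVC(kernel="linear", C=C), X[:, ranking[:s]], y, inner_folds, seed
            )
            if acc > best_acc + 1e-12:  # ties keep the smaller subset
                best_acc, size = acc, s
    return ranking, ranking[:size]


def train_svm(
    X: np.ndarray, y: np.ndarray, p: ProtocolParams, seed: int | None = None
) -> tuple[SVC, dict]:
    """Grid-search C (and gamma for RBF) by inner stratified CV, refit on all.

    Ties prefer the smallest C, then the smallest gamma. ``X`` holds the
    selected, standardized features.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValidationError("cannot train on a single-class split")
    seed = p.seed if seed is None else seed
    gammas: tuple = ("scale",) if p.kernel == "linear" else tuple(sorted(p.gamma_grid))
    best = None
    for C in sorted(p.C_grid):
        for gamma in gammas:
            clf = SVC(kernel=p.kernel, C=C, gamma=gamma)
            acc = _inner_cv_accuracy(clf, X, y, p.inner_folds, seed)
            if best is None or acc > best[0] + 1e-12:
                best = (acc, C, gamma)
    _, C, gamma = best
    clf = SVC(kernel=p.kernel, C=C, gamma=gamma).fit(X, y)
    params = {"C": C} if p.kernel == "linear" else {"C": C, "gamma": gamma}
    params["kernel"] = p.kernel
    return clf, params


def evaluate_fold(
    classifier, X_test: np.ndarray, y_test: np.ndarray, repeat: int = 0, fold: int = 0,
    approach: str = "", selected: Sequence[int] = (), hyperparameters: dict | None = None,
) -> CvRunResult:
    """Confusion counts on a held-out fold; the case group is positive (1)."""
    X_test = np.asarray(X_test, dtype=float)
    y_test = np.asarray(y_test)
    if X_test.shape[1] != getattr(classifier, "n_features_in_", X_test.shape[1]):
        raise ShapeError(
            f"test features have {X_test.shape[1]} columns, "
            f"classifier expects {classifier.n_features_in_}"
        )
    pred = classifier.predict(X_test)
    return CvRunResult(
        tp=int(np.sum((pred == 1) & (y_test == 1))),
        fp=int(np.sum((pred == 1) & (y_test == 0))),
        tn=int(np.sum((pred == 0) & (y_test == 0))),
        fn=int(np.sum((pred == 0) & (y_test == 1))),
        repeat=repeat,
        fold=fold,
        approach=approach,
        selected_features=tuple(selected),
        hyperparameters=dict(hyperparameters or {}),
    )


def metrics(run: CvRunResult) -> dict[str, float]:
    """Accuracy, precision, recall, specificity and F1 from confusion counts.

    Zero-denominator metrics are reported as 0 and flagged under
    ``"flags"``.
    """
    tp, fp, tn, fn = run.tp, run.fp, run.tn, run.fn
    total = tp + fp + tn + fn
    flags = []

    def _ratio(num, den, name):
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    accuracy = _ratio(tp + tn, total, "accuracy")
    precision = _ratio(tp, tp + fp, "precision")
    recall = _ratio(tp, tp + fn, "recall")
    specificity = _ratio(tn, tn + fp, "specificity")
    f1 = (
        0.0
        if precision + recall == 0
        else 2 * precision * recall / (precision + recall)
    )
    if precision + recall == 0:
        flags.append("f1")
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "specificity": specificity,
        "f1": f1,
        "flags": flags,
    }


# ---------------------------------------------------------------------------
# Full protocol
# ---------------------------------------------------------------------------

@dataclass
class _SubjectFeaturesSource:
    """Precomputed per-subject ingredients (leakage-free: all are computed
    from the subject's own series only)."""

    subject_id: str
    group: str
    sfc: np.ndarray
    wqcps: list


def prepare_subjects(
    cohort: Sequence[RoiTimeSeries],
    window_seconds: float,
    seg_params: SegmentationParams | None = None,
    sfc_mode: str = "positive_sum",
    step: int = 1,
) -> list[_SubjectFeaturesSource]:
    """Per-subject static strength and WQCPs (independent of any split)."""
    out = []
    for ts in cohort:
        strength = sfc_strength(static_fc(ts), mode=sfc_mode).values
        dfcs = dfcs_from_timeseries(ts, window_seconds, step=step)
        out.append(
            _SubjectFeaturesSource(
                subject_id=ts.subject_id,
                group=ts.group,
                sfc=strength,
                wqcps=extract_wqcps(dfcs, seg_params),
            )
        )
    return out


def _feature_matrix(
    subjects: Sequence[_SubjectFeaturesSource],
    approach: str,
    model,
) -> np.ndarray:
    rows = []
    for s in subjects:
        if approach == "sfc":
            rows.append(s.sfc)
        else:
            fv = dfcp_features(
                s.wqcps, model, s.subject_id, s.group,
                sfc_strength=s.sfc if approach == "combined" else None,
            )
            rows.append(fv.concatenated(include_sfc=(approach == "combined")))
    return np.vstack(rows)


def run_protocol(
    cohort: Sequence[RoiTimeSeries],
    approach: str,
    window_seconds: float,
    p: ProtocolParams,
    seg_params: SegmentationParams | None = None,
    clustering: ClusteringParams | None = None,
    extra_test: Sequence[RoiTimeSeries] | None = None,
    _prepared: Sequence[_SubjectFeaturesSource] | None = None,
) -> list[CvRunResult]:
    """Repeated stratified k-fold evaluation of one approach at one window.

    Per (repeat, fold): cluster the DFCP model on training WQCPs only,
    build features, z-score with training statistics, SVM-RFE, tune and
    train the SVM, and score the held-out fold. Returns
    ``repeats * outer_folds`` :class:`CvRunResult` records (case = positive
    class). An optional fully-held-out ``extra_test`` cohort is scored by
    every fold's classifier; those records carry ``approach`` suffixed with
    ``"+extra"``.
    """
    if approach not in APPROACHES:
        raise ValidationError(f"approach must be one of {APPROACHES}")
    clustering = clustering or ClusteringParams(random_seed=p.seed)
    subjects = (
        list(_prepared)
        if _prepared is not None
        else prepare_subjects(cohort, window_seconds, seg_params, p.sfc_mode)
    )
    extra_subjects = (
        prepare_subjects(extra_test, window_seconds, seg_params, p.sfc_mode)
        if extra_test
        else None
    )
    groups = [s.group for s in subjects]
    y = np.asarray([1 if g == "case" else 0 for g in groups])

    # independent child seeds per (repeat, fold, purpose), all below 2**31
    ss = np.random.SeedSequence(p.seed)
    seeds = ss.generate_state(p.repeats * (p.outer_folds + 1) * 4) % (2**31)
    seed_iter = iter(int(s) for s in seeds)

    results: list[CvRunResult] = []
    for repeat in range(p.repeats):
        fold_seed = next(seed_iter)
        assignment = stratified_folds(groups, p.outer_folds, fold_seed)
        for fold in range(p.outer_folds):
            test_mask = assignment == fold
            train_idx = np.where(~test_mask)[0]
            test_idx = np.where(test_mask)[0]
            cluster_seed = next(seed_iter)
            inner_seed = next(seed_iter)

            model = None
            if approach in ("dfcp", "combined"):
                train_ids = {subjects[i].subject_id for i in train_idx}
                test_ids = {subjects[i].subject_id for i in test_idx}
                if train_ids & test_ids:
                    raise LeakageError(
                        f"subjects in both splits: {sorted(train_ids & test_ids)}"
                    )
                train_wqcps = [
                    w for i in train_idx for w in subjects[i].wqcps
                ]
                for w in train_wqcps:
                    if w.subject_id in test_ids:
                        raise LeakageError(
                            f"test subject {w.subject_id} reached clustering"
                        )
                model = twice_cluster(
                    train_wqcps, replace(clustering, random_seed=cluster_seed)
                )

            X = _feature_matrix(subjects, approach, model)
            scaler = StandardScaler().fit(X[train_idx])
            Xs = scaler.transform(X)

            _, selected = svm_rfe(
                Xs[train_idx], y[train_idx],
                rfe_step=p.rfe_step, select=p.rfe_select,
                inner_folds=p.inner_folds, seed=inner_seed,
            )
            clf, hyper = train_svm(
                Xs[train_idx][:, selected], y[train_idx], p, seed=inner_seed
            )
            results.append(
                evaluate_fold(
                    clf, Xs[test_idx][:, selected], y[test_idx],
                    repeat=repeat, fold=fold, approach=approach,
                    selected=selected, hyperparameters=hyper,
                )
            )
            if extra_subjects is not None:
                Xe = _feature_matrix(extra_subjects, approach, model)
                ye = np.asarray(
                    [1 if s.group == "case" else 0 for s in extra_subjects]
                )
                results.append(
                    evaluate_fold(
                        clf, scaler.transform(Xe)[:, selected], ye,
                        repeat=repeat, fold=fold, approach=approach + "+extra",
                        selected=selected, hyperparameters=hyper,
                    )
                )
    return results
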