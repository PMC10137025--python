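"""Synthetic two-group cohorts with known dynamic and static ground truth.

The generator emulates exactly the structure the pipeline consumes: each
subject's ROI series is a zero-mean Gaussian whose correlation matrix
switches between K latent states along a minimum-dwell Markov chain. Group
differences enter through (a) the chains' stationary state occupancies and
(b) a static connectivity-strength offset for the case group, applied by
scaling the factor loadings of a designated ROI subset when the case-group
state correlation matrices are built. Ground truth (state sequences,
occupancies, informative ROIs) is returned alongside every cohort so
recovery can be scored at any pipeline stage.

Hemodynamics, physiological noise and scanner drift are deliberately not
modeled: every downstream statistic is second-order, so piecewise-constant
Gaussian correlation is the minimal faithful generative model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import DfcpError, RoiTimeSeries, ValidationError, write_roi_timeseries

__all__ = [
    "SyntheticSpec",
    "make_states",
    "transition_matrix",
    "simulate_subject",
    "simulate_cohort",
    "write_cohort",
    "PRESETS",
    "preset",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative parameters for a two-group cohort.

    Defaults are the strong-effect study conditions: 34 subjects per group,
    T=150 samples at TR 2.0 s, 20 ROIs, two latent states with group
    occupancies (0.7, 0.3) vs (0.3, 0.7), and a 0.3 static-strength loading
    offset on the informative ROI subset of the case group.
    """

    n_rois: int = 20
    n_subjects_per_group: int = 34
    T: int = 150
    tr_seconds: float = 2.0
    n_states: int = 2
    factor_rank: int = 3
    hub_loading_scale: float = 2.0
    base_loading_scale: float = 0.3
    occupancy_case: tuple[float, ...] = (0.7, 0.3)
    occupancy_control: tuple[float, ...] = (0.3, 0.7)
    switch_rate: float = 0.4
    dwell_min: int = 5
    static_strength_shift: float = 0.3
    n_informative_rois: int = 4
    noise_sd: float = 0.1
    min_state_distance: float = 2.0
    seed: int = 0
    # optional heterogeneity overrides (e.g. different scanner for cases)
    tr_seconds_case: float | None = None
    T_case: int | None = None

    def __post_init__(self):
        if self.n_rois < 2 or self.T < 2:
            raise ValidationError("need n_rois >= 2 and T >= 2")
        if self.factor_rank >= self.n_rois:
            raise ValidationError("factor_rank must be below n_rois")
        for occ in (self.occupancy_case, self.occupancy_control):
            if len(occ) != self.n_states:
                raise ValidationError("occupancy length must equal n_states")
            if abs(sum(occ) - 1.0) > 1e-8 or any(o < 0 for o in occ):
                raise ValidationError("occupancies must be a distribution")
        if self.dwell_min < 1:
            raise ValidationError("dwell_min must be >= 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")
        if not (0 < self.switch_rate <= 1):
            raise ValidationError("switch_rate must lie in (0, 1]")


def _corr_from_loadings(L: np.ndarray, uniq: np.ndarray) -> np.ndarray:
    cov = L @ L.T + np.diag(uniq)
    d = np.sqrt(np.diagonal(cov))
    return cov / np.outer(d, d)


def make_states(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray]:
    """Build per-state correlation matrices for both groups.

    States model hub reconfiguration: the ROIs are split into ``n_states``
    contiguous blocks and state k gives block k strong factor loadings
    (``hub_loading_scale``) against a weak background
    (``base_loading_scale``), plus unit diagonal uniqueness, rescaled to a
    correlation matrix. A state switch therefore moves which ROIs carry
    high connectivity strength -- the signal the dFCS pipeline consumes.
    States are resampled (bounded retries) until every pairwise Frobenius
    distance exceeds ``min_state_distance``. The case-group variant of each
    state scales the informative ROIs' loadings by
    ``1 + static_strength_shift``, raising those ROIs' correlations and
    hence their static strength.

    Returns ``(control_states, case_states, informative_rois)``.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    informative = np.arange(min(spec.n_informative_rois, spec.n_rois))
    blocks = np.array_split(np.arange(spec.n_rois), spec.n_states)
    for _ in range(200):
        loadings = []
        for k in range(spec.n_states):
            L = rng.normal(
                0.0, spec.base_loading_scale, size=(spec.n_rois, spec.factor_rank)
            )
            L[blocks[k]] = rng.normal(
                0.0, spec.hub_loading_scale, size=(len(blocks[k]), spec.factor_rank)
            )
            loadings.append(L)
        uniq = np.full(spec.n_rois, 1.0)
        control = [_corr_from_loadings(L, uniq) for L in loadings]
        dists = [
            np.linalg.norm(control[i] - control[j])
            for i in range(spec.n_states)
            for j in range(i + 1, spec.n_states)
        ]
        if not dists or min(dists) >= spec.min_state_distance:
            case = []
            for L in loadings:
                Lc = L.copy()
                Lc[informative, :] *= 1.0 + spec.static_strength_shift
                case.append(_corr_from_loadings(Lc, uniq))
            return control, case, informative
    raise DfcpError(
        f"could not draw {spec.n_states} states with pairwise distance "
        f">= {spec.min_state_distance} after 200 attempts"
    )


def transition_matrix(occupancy: Sequence[float], switch_rate: float) -> np.ndarray:
    """Row-stochastic chain with the given stationary distribution.

    Off-diagonal ``P[i, j] = switch_rate * pi_j``; the diagonal absorbs the
    remainder, so smaller ``switch_rate`` means longer dwells.
    """
    pi = np.asarray(list(occupancy), dtype=float)
    K = len(pi)
    P = switch_rate * np.tile(pi, (K, 1))
    np.fill_diagonal(P, 0.0)
    np.fill_diagonal(P, 1.0 - P.sum(axis=1))
    if np.any(np.diagonal(P) < 0):
        raise ValidationError("switch_rate too large for this occupancy")
    return P


def _sample_states(
    P: np.ndarray, pi: np.ndarray, T: int, dwell_min: int, rng: np.random.Generator
) -> np.ndarray:
    """Markov path with transitions suppressed until dwell_min is reached."""
    K = len(pi)
    states = np.empty(T, dtype=int)
    current = int(rng.choice(K, p=pi))
    dwell = 0
    for t in range(T):
        states[t] = current
        dwell += 1
        if dwell >= dwell_min:
            nxt = int(rng.choice(K, p=P[current]))
            if nxt != current:
                current = nxt
                dwell = 0
    return states


def simulate_subject(
    spec: SyntheticSpec,
    group: str,
    seed: int,
    subject_id: str | None = None,
    states_by_group: tuple[list[np.ndarray], list[np.ndarray]] | None = None,
) -> tuple[RoiTimeSeries, np.ndarray]:
    """One subject's series plus its ground-truth state sequence.

    Observations within a dwell are zero-mean multivariate normal with the
    dwelling state's (group-specific) correlation matrix, plus isotropic
    measurement noise of sd ``noise_sd``.
    """
    rng = np.random.default_rng(seed)
    if states_by_group is None:
        control_states, case_states, _ = make_states(spec)
    else:
        control_states, case_states = states_by_group
    corrs = case_states if group == "case" else control_states
    occ = np.asarray(spec.occupancy_case if group == "case" else spec.occupancy_control)
    P = transition_matrix(occ, spec.switch_rate)
    T = spec.T_case if (group == "case" and spec.T_case) else spec.T
    tr = (
        spec.tr_seconds_case
        if (group == "case" and spec.tr_seconds_case)
        else spec.tr_seconds
    )

    states = _sample_states(P, occ, T, spec.dwell_min, rng)
    chols = [np.linalg.cholesky(c + 1e-10 * np.eye(spec.n_rois)) for c in corrs]
    z = rng.standard_normal((T, spec.n_rois))
    values = np.empty((T, spec.n_rois))
    for t in range(T):
        values[t] = chols[states[t]] @ z[t]
    if spec.noise_sd > 0:
        values += spec.noise_sd * rng.standard_normal((T, spec.n_rois))

    ts = RoiTimeSeries(
        values=values,
        tr_seconds=tr,
        subject_id=subject_id or f"{group}-{seed}",
        group=group,
        cohort="synthetic",
    )
    return ts, states


def simulate_cohort(
    spec: SyntheticSpec,
) -> tuple[list[RoiTimeSeries], dict]:
    """A full two-group cohort with its ground-truth record.

    Per-subject seeds derive from the master seed (reproducible and below
    2**31); the ground truth carries planted occupancies, informative ROIs
    and each subject's state sequence and empirical occupancy.
    """
    control_states, case_states, informative = make_states(spec)
    ss = np.random.SeedSequence(spec.seed)
    child_seeds = ss.generate_state(2 * spec.n_subjects_per_group) % (2**31)

    subjects: list[RoiTimeSeries] = []
    truth: dict = {
        "seed": spec.seed,
        "occupancy_case": list(spec.occupancy_case),
        "occupancy_control": list(spec.occupancy_control),
        "informative_rois": informative.tolist(),
        "static_strength_shift": spec.static_strength_shift,
        "subjects": {},
    }
    i = 0
    for group in ("case", "control"):
        for k in range(spec.n_subjects_per_group):
            sid = f"{group}-{k:03d}"
            ts, states = simulate_subject(
                spec, group, int(child_seeds[i]), subject_id=sid,
                states_by_group=(control_states, case_states),
            )
            subjects.append(ts)
            occ_emp = np.bincount(states, minlength=spec.n_states) / len(states)
            truth["subjects"][sid] = {
                "group": group,
                "states": states.tolist(),
                "empirical_occupancy": occ_emp.tolist(),
            }
            i += 1
    return subjects, truth


def write_cohort(
    subjects: Sequence[RoiTimeSeries], truth: dict, out_dir: str | Path
) -> Path:
    """Write per-subject TSV+sidecar files, a manifest, and the ground truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ts in subjects:
        fname = f"{ts.subject_id}.tsv"
        write_roi_timeseries(ts, out_dir / fname)
        rows.append(
            {"subject_id": ts.subject_id, "group": ts.group, "path": fname,
             "tr_seconds": ts.tr_seconds}
        )
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    (out_dir / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return manifest


def _null_spec(seed: int) -> SyntheticSpec:
    return SyntheticSpec(
        occupancy_case=(0.5, 0.5),
        occupancy_control=(0.5, 0.5),
        static_strength_shift=0.0,
        seed=seed,
    )


PRESETS = {
    # the strong-effect conditions are the spec defaults
    "strong-effect": lambda seed: SyntheticSpec(seed=seed),
    # identical generative process for both groups: classification should
    # hover at chance
    "null": _null_spec,
    # full-scale shape: 246 ROIs, case scanner at TR 3.0 s
    "paper-shaped": lambda seed: SyntheticSpec(
        n_rois=246,
        n_informative_rois=20,
        factor_rank=10,
        min_state_distance=10.0,
        tr_seconds_case=3.0,
        T_case=150,
        T=130,
        seed=seed,
    ),
}


def preset(name: str, seed: int = 0) -> SyntheticSpec:
    """Look up a named cohort preset."""
    if name not in PRESETS:
        raise ValidationError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    return PRESETS[name](seed)
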