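"""Linear linkage between the late-preparatory and mid-movement states.

Even when preparation and movement occupy orthogonal subspaces, the two
computations can be lawfully linked: the pattern of states across conditions
in the preparatory subspace can predict the pattern in the movement
subspace.  This module fits X_move ~ W X_prep by least squares (no
intercept: states are cross-condition centered by preprocessing), evaluates
generalization by leave-one-out cross-validation over conditions, and
compares the fit against a null in which each preparatory dimension's values
are shuffled independently across conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

#: default readout times (ms relative to the anchoring event)
T_PREP_MS = 450.0   # end of the preparatory epoch, after target onset
T_MOVE_MS = 100.0   # middle of the movement epoch, after movement onset


@dataclass
class LinkResult:
    W: np.ndarray
    r_squared: float
    r_squared_loocv: float
    shuffle_distribution: np.ndarray
    p_value: float
    shuffle_median: float
    shuffle_ci95: tuple
    t_prep_ms: float = T_PREP_MS
    t_move_ms: float = T_MOVE_MS


def state_at(
    trajectories: np.ndarray,
    time_ms: np.ndarray,
    at_ms: float,
    anchor_ms: float = 0.0,
) -> np.ndarray:
    """Per-condition state of (d, C, T) trajectories at anchor + at_ms.

    Off-grid times resolve to the nearest stored sample with a warning.
    """
    time_ms = np.asarray(time_ms, float)
    target = anchor_ms + at_ms
    if target < time_ms[0] - 1e-9 or target > time_ms[-1] + 1e-9:
        raise ValueError(f"requested time {target} ms outside [{time_ms[0]}, {time_ms[-1]}]")
    k = int(np.argmin(np.abs(time_ms - target)))
    if abs(time_ms[k] - target) > 1e-6:
        warnings.warn(
            f"time {target} ms is off the sampling grid; using nearest sample "
            f"at {time_ms[k]} ms"
        )
    return trajectories[:, :, k]


def _check_centered(x: np.ndarray, name: str) -> None:
    scale = np.abs(x).max()
    if scale > 0 and np.abs(x.mean(axis=1)).max() > 1e-6 * scale:
        raise ValueError(
            f"{name} is not cross-condition centered; the no-intercept fit "
            "assumes centered states (preprocess the response first)"
        )


def fit_linear_map(
    x_prep: np.ndarray, x_move: np.ndarray, require_centered: bool = False
) -> tuple:
    """Least-squares W minimizing ||X_move - W X_prep||_F, and its R^2.

    R^2 is pooled over all matrix entries: 1 - SSE / ||X_move||^2.  A
    rank-deficient X_prep yields the minimum-norm solution with a warning.
    """
    x_prep = np.asarray(x_prep, float)
    x_move = np.asarray(x_move, float)
    d_prep, c = x_prep.shape
    if x_move.shape[1] != c:
        raise ValueError("X_prep and X_move must have the same number of conditions")
    if c < d_prep + 1:
        raise ValueError(f"need at least d_prep+1={d_prep + 1} conditions, got {c}")
    if require_centered:
        _check_centered(x_prep, "X_prep")
        _check_centered(x_move, "X_move")
    if np.linalg.matrix_rank(x_prep) < d_prep:
        warnings.warn("X_prep is rank-deficient; returning the minimum-norm solution")
    w = x_move @ np.linalg.pinv(x_prep)
    sse = float(np.sum((x_move - w @ x_prep) ** 2))
    total = float(np.sum(x_move**2))
    r2 = 1.0 - sse / total if total > 0 else 0.0
    return w, r2


def loocv_r2(x_prep: np.ndarray, x_move: np.ndarray) -> float:
    """Leave-one-condition-out cross-validated R^2, pooled over held-out
    predictions: 1 - sum of held-out SSE / ||X_move||^2."""
    x_prep = np.asarray(x_prep, float)
    x_move = np.asarray(x_move, float)
    d_prep, c = x_prep.shape
    if c < d_prep + 2:
        raise ValueError(f"LOOCV needs at least d_prep+2={d_prep + 2} conditions, got {c}")
    sse = 0.0
    for held in range(c):
        mask = np.arange(c) != held
        w, _ = fit_linear_map(x_prep[:, mask], x_move[:, mask])
        pred = w @ x_prep[:, held]
        sse += float(np.sum((x_move[:, held] - pred) ** 2))
    total = float(np.sum(x_move**2))
    return 1.0 - sse / total if total > 0 else 0.0


def shuffle_null_r2(
    x_prep: np.ndarray,
    x_move: np.ndarray,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> dict:
    """Condition-shuffle null for the linkage R^2.

    Each preparatory dimension's values are permuted independently across
    conditions, the decoder is refit, and its (in-sample) R^2 recorded.  The
    one-tailed p counts shuffles with R^2 at least the observed value.
    """
    if n_shuffles < 100:
        raise ValueError("use at least 100 shuffles")
    x_prep = np.asarray(x_prep, float)
    x_move = np.asarray(x_move, float)
    _, observed = fit_linear_map(x_prep, x_move)
    if np.allclose(x_prep, x_prep[:, :1]):
        warnings.warn("X_prep has zero cross-condition spread; shuffle null is degenerate")
    rng = np.random.default_rng(seed)
    c = x_prep.shape[1]
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        shuffled = np.vstack([row[rng.permutation(c)] for row in x_prep])
        _, null[s] = fit_linear_map(shuffled, x_move)
    p = float(np.mean(null >= observed))
    return {
        "observed": observed,
        "null": null,
        "p": p,
        "median": float(np.median(null)),
        "ci95": (float(np.percentile(null, 2.5)), float(np.percentile(null, 97.5))),
    }


def link_analysis(
    prep_traj: np.ndarray,
    move_traj: np.ndarray,
    time_ms: np.ndarray,
    target_onset_ms: float,
    move_onset_ms: float,
    n_shuffles: int = 1000,
    seed: int = 0,
    t_prep_ms: float = T_PREP_MS,
    t_move_ms: float = T_MOVE_MS,
) -> LinkResult:
    """Full preparatory-to-movement linkage analysis on projected trajectories."""
    x_prep = state_at(prep_traj, time_ms, t_prep_ms, anchor_ms=target_onset_ms)
    x_move = state_at(move_traj, time_ms, t_move_ms, anchor_ms=move_onset_ms)
    w, r2 = fit_linear_map(x_prep, x_move)
    r2_cv = loocv_r2(x_prep, x_move)
    null = shuffle_null_r2(x_prep, x_move, n_shuffles=n_shuffles, seed=seed)
    return LinkResult(
        W=w,
        r_squared=r2,
        r_squared_loocv=r2_cv,
        shuffle_distribution=null["null"],
        p_value=null["p"],
        shuffle_median=null["median"],
        shuffle_ci95=null["ci95"],
        t_prep_ms=t_prep_ms,
        t_move_ms=t_move_ms,
    )
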