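"""Joint identification of mutually orthogonal preparatory and movement subspaces.

Epoch-wise PCA yields two bases that are *nearly* orthogonal in motor-cortex
data, but interpretation of projections is simplest when they are exactly
orthogonal.  This module maximizes the normalized captured variance

    f(Q_prep, Q_move) = 1/2 [ tr(Q_prep^T C_prep Q_prep) / sum_{i<=d_prep} sigma_i(C_prep)
                            + tr(Q_move^T C_move Q_move) / sum_{i<=d_move} sigma_i(C_move) ]

over *jointly orthonormal* bases ([Q_prep Q_move] has orthonormal columns).
Each term is normalized by the most a basis of that size could capture, so
the objective lies in (0, 1] and is insensitive to the two epochs' relative
variance and dimensionality.

The optimizer alternates block eigen-updates: with one block held fixed, the
other block's optimum is the span of the top eigenvectors of its covariance
compressed into the fixed block's orthogonal complement.  Each half-step
solves its subproblem exactly, so the objective never decreases; multiple
seeded restarts (PCA-based and random) guard against local optima.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .alignment import _as_covariance, sample_random_subspace
from .population import EpochMatrix, PopulationResponse


@dataclass
class SubspacePair:
    """Jointly orthonormal preparatory and movement bases with bookkeeping."""

    Q_prep: np.ndarray
    Q_move: np.ndarray
    objective: float
    objective_trace: np.ndarray
    d_prep: int
    d_move: int
    converged: bool = True

    def __post_init__(self) -> None:
        joint = np.hstack([self.Q_prep, self.Q_move])
        gram = joint.T @ joint
        if not np.allclose(gram, np.eye(joint.shape[1]), atol=1e-10):
            raise ValueError("Q_prep and Q_move must be jointly orthonormal")


def _top_eigvecs(cov: np.ndarray, d: int) -> tuple:
    vals, vecs = np.linalg.eigh(cov)
    return vecs[:, ::-1][:, :d], np.clip(vals[::-1], 0.0, None)


def _complement(basis: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the orthogonal complement of the given columns."""
    n, d = basis.shape
    q, _ = np.linalg.qr(basis, mode="complete")
    return q[:, d:]


def _block_update(cov: np.ndarray, other: np.ndarray, d: int) -> np.ndarray:
    """Optimal d-dim basis for ``cov`` inside the complement of ``other``."""
    v = _complement(other)
    w, _ = _top_eigvecs(v.T @ cov @ v, d)
    return v @ w


def _orient(q: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Fix the within-block rotation/sign indeterminacy: axes ordered by
    captured variance, largest-magnitude loading positive."""
    vals, vecs = np.linalg.eigh(q.T @ cov @ q)
    q = q @ vecs[:, ::-1]
    signs = np.sign(q[np.argmax(np.abs(q), axis=0), np.arange(q.shape[1])])
    signs[signs == 0] = 1.0
    return q * signs


def identify_subspaces(
    c_prep,
    c_move,
    d_prep: int = 2,
    d_move: int = 4,
    restarts: int = 20,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> SubspacePair:
    """Simultaneously fit orthogonal preparatory and movement subspaces.

    Runs ``restarts`` initializations (movement-PCs first, preparatory-PCs
    first, then random jointly-orthonormal frames) of the alternating
    eigen-update scheme and returns the best.  Convergence is declared when
    the relative objective change drops below ``tol``; ties between restarts
    resolve to the highest objective, then the earliest restart.
    """
    c_prep = _as_covariance(c_prep)
    c_move = _as_covariance(c_move)
    if c_prep.shape != c_move.shape:
        raise ValueError("covariances must agree in dimension")
    n = c_prep.shape[0]
    if d_prep + d_move > n:
        raise ValueError(f"d_prep + d_move = {d_prep + d_move} exceeds N = {n}")

    _, vals_p = _top_eigvecs(c_prep, d_prep)
    _, vals_m = _top_eigvecs(c_move, d_move)
    denom_p = vals_p[:d_prep].sum()
    denom_m = vals_m[:d_move].sum()
    if denom_p <= 0 or denom_m <= 0:
        raise ValueError("each epoch covariance must have positive top-d variance")

    def objective(qp, qm):
        return 0.5 * (
            np.einsum("nd,nm,md->", qp, c_prep, qp) / denom_p
            + np.einsum("nd,nm,md->", qm, c_move, qm) / denom_m
        )

    rng = np.random.default_rng(seed)
    best = None
    for r in range(restarts):
        if r == 0:  # movement PCs first
            qm, _ = _top_eigvecs(c_move, d_move)
            qp = _block_update(c_prep, qm, d_prep)
        elif r == 1:  # preparatory PCs first
            qp, _ = _top_eigvecs(c_prep, d_prep)
            qm = _block_update(c_move, qp, d_move)
        else:
            frame, _ = np.linalg.qr(rng.standard_normal((n, d_prep + d_move)))
            qp, qm = frame[:, :d_prep], frame[:, d_prep:]
        trace = [objective(qp, qm)]
        converged = False
        for _ in range(max_iter):
            qp = _block_update(c_prep, qm, d_prep)
            qm = _block_update(c_move, qp, d_move)
            trace.append(objective(qp, qm))
            if trace[-1] - trace[-2] < tol * max(abs(trace[-2]), 1e-300):
                converged = True
                break
        cand = (trace[-1], converged, qp, qm, np.array(trace))
        if best is None or cand[0] > best[0] + 1e-15:
            best = cand
    obj, converged, qp, qm, trace = best
    if not converged:
        warnings.warn("subspace identification did not converge; returning best iterate")
    return SubspacePair(
        Q_prep=_orient(qp, c_prep),
        Q_move=_orient(qm, c_move),
        objective=float(obj),
        objective_trace=trace,
        d_prep=d_prep,
        d_move=d_move,
        converged=converged,
    )


def project(resp: PopulationResponse, basis: np.ndarray) -> np.ndarray:
    """Project a population response onto a basis: (d, C, T) trajectories."""
    basis = np.asarray(basis, float)
    if basis.shape[0] != resp.n_neurons:
        raise ValueError("basis rows must match the number of neurons")
    return np.einsum("nd,nct->dct", basis, resp.rates)


def subspace_epoch_variance(
    pair: SubspacePair,
    prep: EpochMatrix,
    move: EpochMatrix,
    c_full=None,
    n_samples: int = 1000,
    seed: int = 0,
) -> dict:
    """Percent variance of each epoch captured by each subspace, with a
    Monte Carlo significance against random subspaces of equal dimension.

    Returns a dict with a 2x2 ``table`` (rows: prep/move subspace; columns:
    prep/move epoch; percent of that epoch's total variance) and one-tailed
    p-values for the two own-epoch entries, counting random subspaces that
    capture at least as much variance.
    """
    from .alignment import variance_captured

    cp, cm = prep.covariance, move.covariance
    table = np.zeros((2, 2))
    for i, q in enumerate((pair.Q_prep, pair.Q_move)):
        for j, cov in enumerate((cp, cm)):
            table[i, j] = variance_captured(cov, q)[1]
    if c_full is None:
        # pooled covariance over both epochs' columns
        joint = np.hstack([prep.data, move.data])
        joint = joint - joint.mean(axis=1, keepdims=True)
        c_full = joint @ joint.T / (joint.shape[1] - 1)
    c_full = _as_covariance(c_full)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(2)
    for _ in range(n_samples):
        qp_r = sample_random_subspace(c_full, pair.d_prep, rng)
        qm_r = sample_random_subspace(c_full, pair.d_move, rng)
        exceed[0] += variance_captured(cp, qp_r)[1] >= table[0, 0]
        exceed[1] += variance_captured(cm, qm_r)[1] >= table[1, 1]
    return {
        "table": table,
        "p_prep": float(exceed[0] / n_samples),
        "p_move": float(exceed[1] / n_samples),
        "n_samples": n_samples,
    }
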