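"""Epoch-wise PCA, the alignment index, and its random-subspace null.

The alignment index quantifies how much of the preparatory-epoch data
variance lies inside a tested d-dimensional basis, relative to the most any
d-dimensional basis could capture:

    A = trace(D^T C_prep D) / sum_{i=1..d} sigma_i(C_prep)

where D holds the top-d movement-epoch PCs and sigma_i are the descending
eigenvalues of C_prep.  A = 0 when the tested span is orthogonal to the
preparatory activity, A = 1 when it coincides with the top-d prep-PCs.

Because even random subspaces of a low-dimensional dataset capture variance,
the observed index is compared against a Monte Carlo null of subspaces drawn
at random *from the covariance of the data across all task times*: each null
basis is the QR-orthonormalization of C_full^{1/2} W with W standard normal,
so the draws concentrate on directions the population actually visits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .population import EpochMatrix

#: absolute tolerance used when ranking the observed index inside the null;
#: makes percentiles well-defined on rank-degenerate data where observed and
#: null indices tie at 1 to machine precision.
TIE_ATOL = 1e-9


@dataclass
class PCBasis:
    """Top principal components of one epoch: orthonormal columns in neuron space."""

    vectors: np.ndarray
    singular_values: np.ndarray
    variance_captured: np.ndarray
    epoch: str = ""

    def __post_init__(self) -> None:
        gram = self.vectors.T @ self.vectors
        if not np.allclose(gram, np.eye(self.vectors.shape[1]), atol=1e-10):
            raise ValueError("PC basis columns are not orthonormal")


@dataclass
class AlignmentResult:
    """Observed alignment index with its Monte Carlo random-subspace null."""

    index: float
    d: int
    null_distribution: np.ndarray
    percentile: float
    p_one_tailed: float
    null_median: float
    null_ci95: tuple

    @property
    def n_samples(self) -> int:
        return self.null_distribution.size


def _as_covariance(c) -> np.ndarray:
    if isinstance(c, EpochMatrix):
        return c.covariance
    c = np.asarray(c, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("covariance must be a square matrix")
    return c


def _effective_rank(eigvals: np.ndarray) -> int:
    if eigvals.size == 0 or eigvals[0] <= 0:
        return 0
    return int(np.sum(eigvals > 1e-12 * eigvals[0]))


def epoch_pcs(epoch, d: int, name: str = None) -> PCBasis:
    """Top-d eigenvectors of the epoch covariance with captured variance."""
    cov = _as_covariance(epoch)
    vals, vecs = np.linalg.eigh(cov)
    vals = np.clip(vals[::-1], 0.0, None)
    vecs = vecs[:, ::-1]
    rank = _effective_rank(vals)
    if d > rank:
        raise ValueError(f"requested {d} PCs but the covariance has effective rank {rank}")
    if name is None:
        name = epoch.epoch.name if isinstance(epoch, EpochMatrix) else ""
    return PCBasis(
        vectors=vecs[:, :d],
        singular_values=vals[:d],
        variance_captured=100.0 * vals[:d] / vals.sum(),
        epoch=name,
    )


def variance_captured(cov, basis: np.ndarray):
    """Per-dimension and total percent of data variance inside a basis."""
    cov = _as_covariance(cov)
    basis = np.asarray(basis, dtype=float)
    gram = basis.T @ basis
    if not np.allclose(gram, np.eye(basis.shape[1]), atol=1e-8):
        raise ValueError("basis columns must be orthonormal")
    per_dim = np.einsum("nd,nm,md->d", basis, cov, basis)
    total = np.trace(cov)
    per_dim_pct = 100.0 * per_dim / total
    return per_dim_pct, float(per_dim_pct.sum())


def alignment_index(c_prep, d_basis: np.ndarray, d: int = None) -> float:
    """Trace-ratio alignment of a tested basis with the preparatory covariance."""
    cov = _as_covariance(c_prep)
    d_basis = np.asarray(d_basis, dtype=float)
    if d is None:
        d = d_basis.shape[1]
    if d_basis.shape[1] != d:
        raise ValueError("basis has a different number of columns than d")
    gram = d_basis.T @ d_basis
    if not np.allclose(gram, np.eye(d), atol=1e-8):
        raise ValueError("tested basis must have orthonormal columns")
    vals = np.clip(np.linalg.eigvalsh(cov)[::-1], 0.0, None)
    rank = _effective_rank(vals)
    if d > rank:
        raise ValueError(f"d={d} exceeds the covariance effective rank {rank}")
    num = float(np.einsum("nd,nm,md->", d_basis, cov, d_basis))
    den = float(vals[:d].sum())
    return num / den


def _sqrt_psd(cov: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(cov)
    vals = np.clip(vals, 0.0, None)
    return vecs * np.sqrt(vals) @ vecs.T


def sample_random_subspace(c_full, d: int, rng: np.random.Generator) -> np.ndarray:
    """One random d-frame weighted by the full data covariance.

    Draws d vectors v_k = C_full^{1/2} w_k with w_k ~ N(0, I) and
    orthonormalizes them by QR; the resulting span concentrates on the
    high-variance directions of C_full.
    """
    cov = _as_covariance(c_full)
    vals = np.linalg.eigvalsh(cov)
    rank = _effective_rank(np.clip(vals[::-1], 0.0, None))
    if d > rank:
        raise ValueError(f"d={d} exceeds rank {rank} of the full covariance")
    root = _sqrt_psd(cov)
    q, _ = np.linalg.qr(root @ rng.standard_normal((cov.shape[0], d)))
    return q


def _null_stats(observed: float, null: np.ndarray):
    below = np.sum(null <= observed + TIE_ATOL)
    percentile = float(below) / null.size
    p = percentile  # one-tailed, misalignment direction
    return percentile, p


def random_alignment_null(
    c_full,
    c_prep,
    c_move,
    d: int,
    n_samples: int = 10_000,
    seed: int = 0,
) -> dict:
    """Alignment index of each epoch against covariance-matched random frames.

    For each of ``n_samples`` draws, a random d-frame (sampled from the full
    data covariance) stands in for the tested basis and the alignment index
    is recomputed — against C_prep (surrogate move-PCs) and, symmetrically,
    against C_move (surrogate prep-PCs).  The observed indices use the true
    top-d PCs of the other epoch.  One-tailed p-values count null samples at
    or below the observed index (misalignment direction).

    Returns ``{"prep": AlignmentResult, "move": AlignmentResult}``.
    """
    import warnings

    if n_samples < 100:
        warnings.warn("fewer than 100 null samples gives a very coarse percentile")
    c_full = _as_covariance(c_full)
    c_prep = _as_covariance(c_prep)
    c_move = _as_covariance(c_move)
    if not (c_full.shape == c_prep.shape == c_move.shape):
        raise ValueError("covariances must agree in dimension")
    rng = np.random.default_rng(seed)
    root = _sqrt_psd(c_full)
    n = c_full.shape[0]

    obs_prep = alignment_index(c_prep, epoch_pcs(c_move, d).vectors)
    obs_move = alignment_index(c_move, epoch_pcs(c_prep, d).vectors)

    den_prep = np.clip(np.linalg.eigvalsh(c_prep)[::-1], 0, None)[:d].sum()
    den_move = np.clip(np.linalg.eigvalsh(c_move)[::-1], 0, None)[:d].sum()
    null_prep = np.empty(n_samples)
    null_move = np.empty(n_samples)
    for k in range(n_samples):
        q, _ = np.linalg.qr(root @ rng.standard_normal((n, d)))
        null_prep[k] = np.einsum("nd,nm,md->", q, c_prep, q) / den_prep
        q, _ = np.linalg.qr(root @ rng.standard_normal((n, d)))
        null_move[k] = np.einsum("nd,nm,md->", q, c_move, q) / den_move

    out = {}
    for key, obs, null in (("prep", obs_prep, null_prep), ("move", obs_move, null_move)):
        percentile, p = _null_stats(obs, null)
        out[key] = AlignmentResult(
            index=float(obs),
            d=d,
            null_distribution=null,
            percentile=percentile,
            p_one_tailed=p,
            null_median=float(np.median(null)),
            null_ci95=(float(np.percentile(null, 2.5)), float(np.percentile(null, 97.5))),
        )
    return out
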