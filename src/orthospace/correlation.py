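"""Cross-condition correlation structure and the epoch-preference index.

If the same population subspace is occupied during two epochs, neuron pairs
that covary across conditions in one epoch also covary in the other, and the
two pairwise correlation matrices look alike; orthogonal subspaces scramble
the correlation structure instead.  The epoch-preference index asks the
complementary single-neuron question — whether separate subpopulations are
active in the two epochs — via the bimodality (Hartigan dip) of a bounded
contrast between each neuron's normalized tuning strength in the two epochs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dip import dip_statistic, dip_test
from .population import EpochDef, EpochMatrix, PopulationResponse, resolve_epoch_times


@dataclass
class CorrelationResult:
    """Per-epoch pairwise correlation matrices and their across-epoch similarity."""

    corr_prep: np.ndarray
    corr_move: np.ndarray
    r_squared: float
    r_squared_ci: tuple
    r_squared_sd: float
    bootstrap_distribution: np.ndarray
    excluded_neurons: np.ndarray


@dataclass
class EpochPreferenceResult:
    index: np.ndarray
    s_prep: np.ndarray
    s_move: np.ndarray
    dip_statistic: float
    p_value: float


def epoch_correlation(epoch) -> tuple:
    """Pearson correlation between neurons across the C*T epoch columns.

    Returns ``(corr, excluded)``: zero-variance neurons (e.g. exactly silent
    in the epoch, where correlation is undefined) are dropped from the matrix
    and reported by index.
    """
    data = epoch.data if isinstance(epoch, EpochMatrix) else np.asarray(epoch, float)
    if data.shape[1] < 3:
        raise ValueError("need at least 3 columns to correlate neurons")
    variances = data.var(axis=1)
    excluded = np.where(variances == 0.0)[0]
    kept = np.where(variances > 0.0)[0]
    corr = np.corrcoef(data[kept])
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr, excluded


def correlation_similarity(
    corr_prep: np.ndarray,
    corr_move: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """R-squared between the paired off-diagonal entries of two correlation
    matrices, with a neuron-resampling bootstrap CI.

    The bootstrap resamples neurons (not pairs) so the dependence between
    pairs sharing a neuron is respected; duplicated-neuron self-pairs are
    dropped from each resample.
    """
    corr_prep = np.asarray(corr_prep, float)
    corr_move = np.asarray(corr_move, float)
    if corr_prep.shape != corr_move.shape:
        raise ValueError("correlation matrices must have matching shapes")
    n = corr_prep.shape[0]
    if n < 3:
        raise ValueError("need at least 3 neurons")
    iu = np.triu_indices(n, k=1)

    def r2(cp, cm, rows):
        a = cp[np.ix_(rows, rows)][iu_of(len(rows))]
        b = cm[np.ix_(rows, rows)][iu_of(len(rows))]
        keep = np.array(rows)[:, None] != np.array(rows)[None, :]
        keep = keep[iu_of(len(rows))]
        a, b = a[keep], b[keep]
        if a.size < 2 or a.std() == 0 or b.std() == 0:
            return np.nan
        return float(np.corrcoef(a, b)[0, 1] ** 2)

    def iu_of(m):
        return np.triu_indices(m, k=1)

    observed = float(np.corrcoef(corr_prep[iu], corr_move[iu])[0, 1] ** 2)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        rows = rng.integers(0, n, n)
        boot[b] = r2(corr_prep, corr_move, rows)
    boot = boot[np.isfinite(boot)]
    return {
        "r_squared": observed,
        "ci": (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5))),
        "sd": float(boot.std(ddof=1)),
        "bootstrap": boot,
    }


def correlation_analysis(
    prep: EpochMatrix, move: EpochMatrix, n_boot: int = 1000, seed: int = 0
) -> CorrelationResult:
    """Correlation matrices for both epochs on the common retained neurons,
    plus their across-epoch R-squared."""
    datap, datam = prep.data, move.data
    varp, varm = datap.var(axis=1), datam.var(axis=1)
    excluded = np.where((varp == 0.0) | (varm == 0.0))[0]
    kept = np.where((varp > 0.0) & (varm > 0.0))[0]
    corr_prep, _ = epoch_correlation(datap[kept])
    corr_move, _ = epoch_correlation(datam[kept])
    sim = correlation_similarity(corr_prep, corr_move, n_boot=n_boot, seed=seed)
    return CorrelationResult(
        corr_prep=corr_prep,
        corr_move=corr_move,
        r_squared=sim["r_squared"],
        r_squared_ci=sim["ci"],
        r_squared_sd=sim["sd"],
        bootstrap_distribution=sim["bootstrap"],
        excluded_neurons=excluded,
    )


def tuning_strength(resp: PopulationResponse, epoch: EpochDef) -> np.ndarray:
    """Per-neuron tuning strength of one epoch.

    The maximum over epoch timepoints of the cross-condition firing-rate
    range, divided by the neuron's average cross-condition range over all
    recorded times.  Neurons with zero range at all times get strength 0.
    """
    idx = resolve_epoch_times(resp, epoch)
    ranges = resp.rates.max(axis=1) - resp.rates.min(axis=1)  # (N, T)
    avg_range = ranges.mean(axis=1)
    epoch_max = ranges[:, idx].max(axis=1)
    out = np.zeros(resp.n_neurons)
    flat = avg_range == 0.0
    if np.any(flat):
        warnings.warn(
            f"{int(flat.sum())} neuron(s) have zero rate range at all times; "
            "tuning strength set to 0"
        )
    out[~flat] = epoch_max[~flat] / avg_range[~flat]
    return out


def epoch_preference_index(s_prep: np.ndarray, s_move: np.ndarray) -> np.ndarray:
    """Bounded contrast of normalized tuning strengths, in [-1, 1].

    Each epoch's strengths are first divided by their mean across neurons, so
    an index of 0 marks a neuron with the population-average ratio of
    preparatory to movement tuning; +1 / -1 mark neurons tuned in only one
    epoch.  Neurons with zero strength in both epochs get NaN.
    """
    s_prep = np.asarray(s_prep, float)
    s_move = np.asarray(s_move, float)
    if np.any(s_prep < 0) or np.any(s_move < 0):
        raise ValueError("tuning strengths must be non-negative")
    if not (np.any(s_prep > 0) and np.any(s_move > 0)):
        raise ValueError("need at least one tuned neuron in each epoch")
    np_hat = s_prep / s_prep.mean()
    nm_hat = s_move / s_move.mean()
    denom = np_hat + nm_hat
    with np.errstate(invalid="ignore"):
        index = (np_hat - nm_hat) / denom
    index[denom == 0.0] = np.nan
    return index


def bimodality_test(index: np.ndarray, n_boot: int = 10_000, seed: int = 0) -> tuple:
    """Hartigan dip statistic of the index distribution and its bootstrap p.

    The p-value is calibrated against uniform null samples of the same size.
    Requires at least 10 finite values; a constant vector returns (0, 1).
    """
    index = np.asarray(index, float)
    index = index[np.isfinite(index)]
    if index.size < 10:
        raise ValueError("need at least 10 values for the dip test")
    return dip_test(index, n_boot=n_boot, seed=seed)


def epoch_preference_analysis(
    resp: PopulationResponse,
    prep_epoch: EpochDef,
    move_epoch: EpochDef,
    n_boot: int = 10_000,
    seed: int = 0,
) -> EpochPreferenceResult:
    s_prep = tuning_strength(resp, prep_epoch)
    s_move = tuning_strength(resp, move_epoch)
    index = epoch_preference_index(s_prep, s_move)
    finite = index[np.isfinite(index)]
    if finite.size >= 10:
        dip, p = bimodality_test(index, n_boot=n_boot, seed=seed)
    else:
        dip, p = dip_statistic(finite), np.nan
    return EpochPreferenceResult(
        index=index, s_prep=s_prep, s_move=s_move, dip_statistic=dip, p_value=p
    )
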