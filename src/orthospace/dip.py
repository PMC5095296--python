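"""Hartigan's dip statistic of unimodality.

The dip of a sample is the smallest sup-norm distance between its empirical
CDF and any unimodal distribution function (convex, then concave, with an
atom allowed at the mode).  It is computed by the classical iterative
greatest-convex-minorant / least-concave-majorant algorithm: the modal
interval is narrowed until the band between the two hulls inside it is no
wider than the deviations already accumulated outside it; the dip is half
the final band width.

A sample that is perfectly unimodal (e.g. strictly increasing ECDF with no
flat stretch wider than its neighbours) has the minimal dip 1/(2n); a
half-and-half mixture of two well-separated points approaches the maximal
dip of 1/4.
"""

from __future__ import annotations

import numpy as np


def _convex_minorant_pointers(x: np.ndarray, low: int, high: int) -> np.ndarray:
    """mn[j] = previous touch point of the greatest convex minorant at j."""
    mn = np.zeros(x.size, dtype=np.intp)
    mn[low] = low
    for j in range(low + 1, high + 1):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            if mnj == low:
                break
            mnmnj = mn[mnj]
            if (x[j] - x[mnj]) * (mnj - mnmnj) < (x[mnj] - x[mnmnj]) * (j - mnj):
                break
            mn[j] = mnmnj
    return mn


def _concave_majorant_pointers(x: np.ndarray, low: int, high: int) -> np.ndarray:
    """mj[k] = next touch point of the least concave majorant at k."""
    mj = np.zeros(x.size, dtype=np.intp)
    mj[high] = high
    for k in range(high - 1, low - 1, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            if mjk == high:
                break
            mjmjk = mj[mjk]
            if (x[mjk] - x[k]) * (mjmjk - mjk) < (x[mjmjk] - x[mjk]) * (mjk - k):
                break
            mj[k] = mjmjk
    return mj


def _fit(count_left: float, x_left: float, x_right: float, rise: float, x: float) -> float:
    if x_right == x_left:
        return count_left
    return count_left + (x - x_left) * rise / (x_right - x_left)


def dip_statistic(values) -> float:
    """Hartigan's dip of a 1-d sample.

    Returns 0 for constant or size<2 samples; otherwise a value in
    [1/(2n), 1/4].
    """
    x = np.sort(np.asarray(values, dtype=float).ravel())
    n = x.size
    if n < 2 or x[0] == x[-1]:
        return 0.0
    # indices are 1-based counts conceptually; work 0-indexed and convert in fits
    low, high = 0, n - 1
    dip = 1.0  # running band width, in counts; 1 count = perfectly unimodal

    while True:
        mn = _convex_minorant_pointers(x, low, high)
        mj = _concave_majorant_pointers(x, low, high)

        # gcm touch points, decreasing from high to low
        gcm = [high]
        while gcm[-1] > low:
            gcm.append(mn[gcm[-1]])
        l_gcm = len(gcm)
        # lcm touch points, increasing from low to high
        lcm = [low]
        while lcm[-1] < high:
            lcm.append(mj[lcm[-1]])
        l_lcm = len(lcm)

        ig, ih = l_gcm - 1, l_lcm - 1
        if l_gcm == 2 and l_lcm == 2:
            d = 1.0
        else:
            # walk both hulls, measuring the band width at every touch point
            d = 0.0
            ix, iv = l_gcm - 2, 1
            while True:
                gcmix, lcmiv = gcm[ix], lcm[iv]
                if gcmix > lcmiv:
                    # next touch along x is on the lcm: band width there
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - _fit(
                        0.0, x[gcmi1], x[gcmix], gcmix - gcmi1, x[lcmiv]
                    )
                    iv += 1
                    if dx >= d:
                        d, ig, ih = dx, ix + 1, iv - 1
                else:
                    # next touch along x is on the gcm
                    lcmiv1 = lcm[iv - 1]
                    dx = _fit(
                        0.0, x[lcmiv1], x[lcmiv], lcmiv - lcmiv1, x[gcmix]
                    ) - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx >= d:
                        d, ig, ih = dx, ix + 1, iv
                ix = max(ix, 0)
                iv = min(iv, l_lcm - 1)
                if gcm[ix] == lcm[iv]:
                    break

        if d <= dip:
            break

        # deviations of the ECDF from the hulls outside the new modal interval
        new_low, new_high = gcm[ig], lcm[ih]
        dl = 0.0
        for a in range(ig, l_gcm - 1):
            right, left = gcm[a], gcm[a + 1]
            for i in range(left, right + 1):
                dev = (i + 1) - (
                    left + _fit(0.0, x[left], x[right], right - left, x[i])
                )
                dl = max(dl, dev)
        du = 0.0
        for a in range(ih, l_lcm - 1):
            left, right = lcm[a], lcm[a + 1]
            for i in range(left, right + 1):
                dev = (
                    left + 1 + _fit(0.0, x[left], x[right], right - left, x[i])
                ) - i
                du = max(du, dev)

        dip = max(dip, dl, du)
        if new_low == low and new_high == high:
            break
        low, high = new_low, new_high

    return dip / (2.0 * n)


def dip_test(values, n_boot: int = 10_000, seed: int = 0) -> tuple:
    """Dip statistic and bootstrap p-value against a uniform null.

    The null distribution of the dip is simulated from uniform samples of
    the same size (the least favourable unimodal case); p is the fraction of
    null dips at least as large as the observed one.  A constant sample has
    dip 0 and p 1.
    """
    values = np.asarray(values, dtype=float).ravel()
    values = values[np.isfinite(values)]
    observed = dip_statistic(values)
    if observed == 0.0:
        return 0.0, 1.0
    rng = np.random.default_rng(seed)
    n = values.size
    null = np.empty(n_boot)
    for b in range(n_boot):
        null[b] = dip_statistic(rng.random(n))
    p = float(np.mean(null >= observed))
    return float(observed), p
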