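"""Exact dip statistic by linear programming, directly from the definition:
dip(F_n) = min over unimodal CDFs G of sup_x |F_n(x) - G(x)|.

For each candidate mode (at a data point, with an atom allowed there, or in
an open interval between points), feasibility of a piecewise-linear G within
delta of the ECDF is a set of linear constraints; minimize delta by LP.
Only for tiny n (oracle use).
"""
import numpy as np
from scipy.optimize import linprog


def dip_lp(x):
    x = np.sort(np.asarray(x, float))
    n = x.size
    # merge ties: weights
    vals, counts = np.unique(x, return_counts=True)
    m = vals.size
    if m == 1:
        return 0.0
    cum = np.cumsum(counts) / n          # F at point (right value)
    left = (np.cumsum(counts) - counts) / n  # F just left of point
    best = np.inf
    # mode at a data point (atom allowed there)
    for k in range(m):
        val = _solve(vals, left, cum, k, "point")
        if val is not None:
            best = min(best, val)
    # mode strictly inside an interval: grid over the mode position
    for k in range(m - 1):
        for frac in np.linspace(0.001, 0.999, 41):
            mode_x = vals[k] + frac * (vals[k + 1] - vals[k])
            val = _solve_interval(vals, left, cum, k, mode_x)
            if val is not None:
                best = min(best, val)
    return best


def _solve_interval(xs, left, cum, k, mode_x):
    """Mode at mode_x in (x_k, x_{k+1}): extra variables gM (left-piece value
    at the mode) and H (post-jump value starting the concave piece)."""
    m = xs.size
    nv = m + 3  # g_0..g_{m-1}, gM, H, delta
    igM, iH, idelta = m, m + 1, m + 2
    A, b = [], []

    def con(coefs, rhs):
        row = np.zeros(nv)
        for i, c in coefs:
            row[i] += c
        A.append(row)
        b.append(rhs)

    for j in range(m):
        con([(j, 1.0), (idelta, -1.0)], left[j])
        con([(j, -1.0), (idelta, -1.0)], -cum[j])
    for j in range(m - 1):
        con([(j, 1.0), (j + 1, -1.0)], 0.0)
    con([(0, -1.0)], 0.0)
    con([(m - 1, 1.0)], 1.0)
    # gM: band on the interval (F there = cum_k), monotone, convex continuation
    con([(igM, 1.0), (idelta, -1.0)], cum[k])
    con([(k, 1.0), (igM, -1.0)], 0.0)  # g_k <= gM
    if k > 0:
        # slope(x_k -> mode) >= slope(x_{k-1} -> x_k)
        d0 = xs[k] - xs[k - 1]
        dm = mode_x - xs[k]
        con([(k, 1.0 * dm + 1.0 * d0), (k - 1, -dm), (igM, -d0)], 0.0)
    # H: jump at the mode, then concave into x_{k+1}
    con([(igM, 1.0), (iH, -1.0)], 0.0)  # gM <= H
    con([(iH, 1.0), (k + 1, -1.0)], 0.0)  # H <= g_{k+1}
    if k + 2 < m:
        # slope(mode -> x_{k+1}) >= slope(x_{k+1} -> x_{k+2})
        d1 = xs[k + 1] - mode_x
        d2 = xs[k + 2] - xs[k + 1]
        con([(k + 2, d1), (k + 1, -(d1 + d2)), (iH, d2)], 0.0)
    # convexity of the left piece among data nodes, concavity of the right
    for j in range(1, k):
        d01, d12 = xs[j] - xs[j - 1], xs[j + 1] - xs[j]
        con([(j + 1, -d01), (j, d01 + d12), (j - 1, -d12)], 0.0)
    for j in range(k + 2, m - 1):
        d01, d12 = xs[j] - xs[j - 1], xs[j + 1] - xs[j]
        con([(j + 1, d01), (j, -(d01 + d12)), (j - 1, d12)], 0.0)
    c = np.zeros(nv)
    c[idelta] = 1.0
    from scipy.optimize import linprog

    res = linprog(c, A_ub=np.array(A), b_ub=np.array(b), bounds=[(None, None)] * nv)
    return res.fun if res.success else None


def _solve(xs, left, cum, k, kind):
    m = xs.size
    # variables: g_0..g_{m-1}, gL (left limit at mode, only for point mode), delta
    extra = 1 if kind == "point" else 0
    nv = m + extra + 1
    idelta = nv - 1
    igL = m if kind == "point" else None
    A, b = [], []

    def con(coefs, rhs):  # coefs . v <= rhs
        row = np.zeros(nv)
        for i, c in coefs:
            row[i] += c
        A.append(row)
        b.append(rhs)

    # bands: g_j <= left_j + delta ; g_j >= cum_j - delta   (non-mode handling)
    for j in range(m):
        if kind == "point" and j == k:
            # value at mode: |g_k - cum_k| <= delta (left limit handled by gL)
            con([(j, 1.0), (idelta, -1.0)], cum[j])
            con([(j, -1.0), (idelta, -1.0)], -cum[j])
        else:
            con([(j, 1.0), (idelta, -1.0)], left[j])
            con([(j, -1.0), (idelta, -1.0)], -cum[j])
    if kind == "point":
        # gL in [left_k - delta, left_k + delta], g_{k-1} <= gL <= g_k
        con([(igL, 1.0), (idelta, -1.0)], left[k])
        con([(igL, -1.0), (idelta, -1.0)], -left[k])
        con([(k, -1.0), (igL, 1.0)], 0.0)  # gL <= g_k
        if k > 0:
            con([(igL, -1.0), (k - 1, 1.0)], 0.0)  # g_{k-1} <= gL
    # monotone
    for j in range(m - 1):
        con([(j, 1.0), (j + 1, -1.0)], 0.0)
    # g_0 >= 0, g_last <= 1
    con([(0, -1.0)], 0.0)
    con([(m - 1, 1.0)], 1.0)

    # convex part / concave part node lists: (x, var index)
    if kind == "point":
        lnodes = [(xs[j], j) for j in range(k)] + [(xs[k], igL)]
        rnodes = [(xs[j], j) for j in range(k, m)]
    else:
        lnodes = [(xs[j], j) for j in range(k + 1)]
        rnodes = [(xs[j], j) for j in range(k + 1, m)]
    # convex: slope(j->j+1) >= slope(j-1->j)
    for nodes, sign in ((lnodes, 1.0), (rnodes, -1.0)):
        for a in range(1, len(nodes) - 1):
            (x0, i0), (x1, i1), (x2, i2) = nodes[a - 1], nodes[a], nodes[a + 1]
            d01, d12 = x1 - x0, x2 - x1
            # convex: (g2-g1)/d12 - (g1-g0)/d01 >= 0  -> multiply by d01*d12>0
            # sign=-1 flips for concavity
            con(
                [(i2, -sign * d01), (i1, sign * (d01 + d12)), (i0, -sign * d12)],
                0.0,
            )
    c = np.zeros(nv)
    c[idelta] = 1.0
    res = linprog(c, A_ub=np.array(A), b_ub=np.array(b), bounds=[(None, None)] * nv)
    return res.fun if res.success else None


if __name__ == "__main__":
    rng = np.random.default_rng(0)
    print("uniform n=10:", dip_lp(rng.random(10)))
    print("two-point:", dip_lp(np.r_[np.zeros(10), np.ones(10)]))
    print("n=2 {0,1}:", dip_lp([0.0, 1.0]))
    print("equally spaced n=6:", dip_lp(np.arange(6) / 5), "expect", 1 / 12)
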