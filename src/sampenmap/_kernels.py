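"""Numba kernels for template-match counting.

The counting loops are O(T^2 * m) per series; the early break on the
Chebyshev test makes the average cost much lower at practical tolerances.
Counts are accumulated over ordered pairs (i, j), i != j, by exploiting
symmetry: each unordered match contributes 2.
"""

import numba
import numpy as np


@numba.njit(cache=True)
def count_matches_1d(x, m, r):
    """Ordered-pair match counts for windows of length m and m+1.

    Template starts run over i = 0 .. T-1 with T = N - m, so the
    (m+1)-window at the last start still fits.  Returns (b, a): matches
    within tolerance r under the Chebyshev distance for the m-window and
    its one-point extension.  a <= b structurally.

    Walks lag diagonals d = j - i: along a diagonal the Chebyshev window
    test "all of |x[t] - x[t+d]| <= r for m consecutive t" reduces to a
    run-length count, which removes the inner dimension loop of the naive
    pairwise formulation.
    """
    n = x.shape[0]
    t = n - m
    b = 0
    a = 0
    for d in range(1, t):
        i_count = t - d  # template starts i = 0 .. i_count-1 pair with j = i + d
        run = 0
        for tpos in range(i_count + m):  # tpos + d <= n - 1
            if abs(x[tpos] - x[tpos + d]) <= r:
                run += 1
            else:
                run = 0
            # m-window starting at i = tpos - m + 1 is fully within r
            i_m = tpos - m + 1
            if run >= m and 0 <= i_m < i_count:
                b += 2
            # (m+1)-window starting at i = tpos - m
            i_m1 = tpos - m
            if run >= m + 1 and 0 <= i_m1 < i_count:
                a += 2
    return b, a


@numba.njit(cache=True)
def count_matches_batch(series, m, r_abs, out):
    """Match counts for a stack of equal-length series.

    series : (S, N) float64; r_abs : (S,) per-series absolute tolerance;
    out : (S, 2) int64 receiving (b, a) per row.
    """
    for s in range(series.shape[0]):
        b, a = count_matches_1d(series[s], m, r_abs[s])
        out[s, 0] = b
        out[s, 1] = a


@numba.njit(cache=True)
def ar1_batch(phi, innovations, out):
    """Simulate a stack of AR(1) series from pre-drawn innovations.

    phi : (S,); innovations : (S, N) iid N(0, sd^2) draws whose first
    column is rescaled here to the stationary marginal sd/sqrt(1-phi^2);
    out : (S, N).
    """
    s_count, n = innovations.shape
    for s in range(s_count):
        p = phi[s]
        out[s, 0] = innovations[s, 0] / np.sqrt(1.0 - p * p)
        for t in range(1, n):
            out[s, t] = p * out[s, t - 1] + innovations[s, t]
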