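"""Independent reference implementations used only by the tests.

Everything here is deliberately naive (double loops, textbook formulas)
and shares no code with the production package, so agreement is
meaningful.
"""

import math

import numpy as np


def brute_force_counts(x, m, r):
    """Exhaustive O(N^2) ordered-pair match counting.

    Both window lengths use template starts i = 1 .. N - m (0-based:
    0 .. N-m-1), self-pairs excluded, Chebyshev distance, match iff
    distance <= r.
    """
    x = list(map(float, x))
    n = len(x)
    t = n - m
    b = a = 0
    for i in range(t):
        for j in range(t):
            if i == j:
                continue
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
            if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) <= r:
                a += 1
    return b, a


def brute_force_sampen(x, m, r_factor):
    """-ln(A/B) with r = r_factor * sample SD, via the brute-force counts."""
    x = np.asarray(x, dtype=float)
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        return None
    b, a = brute_force_counts(x, m, r_factor * sd)
    if b == 0 or a == 0:
        return None
    return -math.log(a / b)


def iid_gaussian_sampen_limit(r_factor):
    """Analytic SampEn limit for iid Gaussian data.

    For iid data each extra template point matches independently with
    p = P(|X - Y| <= r) where X - Y ~ N(0, 2 sigma^2), so
    SampEn -> -ln p = -ln(2 Phi(r_factor / sqrt(2)) - 1).
    """
    from scipy.stats import norm

    return -math.log(2.0 * norm.cdf(r_factor / math.sqrt(2.0)) - 1.0)


def masked_roi_means(values, labels):
    """Per-parcel mean/SD/count over finite voxels, by explicit loop."""
    out = {}
    for lab in sorted(set(labels.ravel()) - {0}):
        vox = [
            float(v)
            for v, l in zip(values.ravel(), labels.ravel())
            if l == lab and np.isfinite(v)
        ]
        if not vox:
            out[int(lab)] = (math.nan, math.nan, 0)
        else:
            mean = sum(vox) / len(vox)
            sd = (
                math.sqrt(sum((v - mean) ** 2 for v in vox) / (len(vox) - 1))
                if len(vox) > 1
                else math.nan
            )
            out[int(lab)] = (mean, sd, len(vox))
    return out


def textbook_pearson(x, y):
    """Pearson r and two-tailed p from the t transform, from scratch."""
    from scipy.stats import t as tdist

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    xm, ym = x - x.mean(), y - y.mean()
    r = float((xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum()))
    t = r * math.sqrt((n - 2) / (1 - r**2))
    p = 2.0 * float(tdist.sf(abs(t), n - 2))
    return r, p
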