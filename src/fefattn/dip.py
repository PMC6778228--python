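"""Hartigan's dip statistic and its bootstrap-calibrated test.

The dip of an empirical distribution function F_n is the smallest sup-norm
distance between F_n and the class of unimodal distribution functions
(convex below the mode, concave above).  The implementation follows the
classical algorithm of Hartigan & Hartigan: alternating greatest-convex-
minorant / least-concave-majorant fits over a shrinking modal interval.
The p-value is calibrated by Monte Carlo against the uniform null — the
asymptotically least-favourable unimodal distribution — at the observed
sample size.
"""

from __future__ import annotations

import numpy as np


def dip_statistic(values) -> float:
    """Hartigan's dip of a one-dimensional sample.

    Bounded below by 1/(2n); larger values indicate departure from
    unimodality.  Degenerate samples (all values equal) return 0.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 1:
        raise ValueError("empty sample")
    if n == 1 or x[0] == x[-1]:
        return 0.0

    # 1-based arrays, mirroring the classical formulation
    xs = np.empty(n + 1)
    xs[1:] = x
    mn = np.zeros(n + 1, dtype=int)
    mj = np.zeros(n + 1, dtype=int)
    gcm = np.zeros(n + 2, dtype=int)
    lcm = np.zeros(n + 2, dtype=int)

    low, high = 1, n
    dip = 1.0  # in units of counts; divided by 2n at the end

    # indices over which combination is necessary for the convex minorant
    mn[1] = 1
    for j in range(2, n + 1):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 1 or (
                (xs[j] - xs[mnj]) * (mnj - mnmnj)
                < (xs[mnj] - xs[mnmnj]) * (j - mnj)
            ):
                break
            mn[j] = mnmnj
    # ... and for the concave majorant
    mj[n] = n
    for k in range(n - 1, 0, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            mjmjk = mj[mjk]
            if mjk == n or (
                (xs[k] - xs[mjk]) * (mjk - mjmjk)
                < (xs[mjk] - xs[mjmjk]) * (k - mjk)
            ):
                break
            mj[k] = mjmjk

    while True:
        # change points of the GCM from high to low
        gcm[1] = high
        i = 1
        while gcm[i] > low:
            gcm[i + 1] = mn[gcm[i]]
            i += 1
        l_gcm = i
        ig = l_gcm
        ix = l_gcm - 1
        # change points of the LCM from low to high
        lcm[1] = low
        i = 1
        while lcm[i] < high:
            lcm[i + 1] = mj[lcm[i]]
            i += 1
        l_lcm = i
        ih = l_lcm
        iv = 2

        # largest distance between GCM and LCM on [low, high]
        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            while True:
                gcmix = gcm[ix]
                lcmiv = lcm[iv]
                if gcmix > lcmiv:
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (xs[lcmiv] - xs[gcmi1]) * (
                        gcmix - gcmi1
                    ) / (xs[gcmix] - xs[gcmi1])
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    lcmiv1 = lcm[iv - 1]
                    dx = (xs[gcmix] - xs[lcmiv1]) * (lcmiv - lcmiv1) / (
                        xs[lcmiv] - xs[lcmiv1]
                    ) - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx > d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 1:
                    ix = 1
                if iv > l_lcm:
                    iv = l_lcm
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0
        if d < dip:
            break

        # dip within the convex-minorant segment
        dip_l = 0.0
        for j in range(ig, l_gcm):
            max_t = 1.0
            jb, je = gcm[j + 1], gcm[j]
            if je - jb > 1 and xs[je] != xs[jb]:
                c = (je - jb) / (xs[je] - xs[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (xs[jj] - xs[jb]) * c
                    if max_t < t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t
        # dip within the concave-majorant segment
        dip_u = 0.0
        for j in range(ih, l_lcm):
            max_t = 1.0
            jb, je = lcm[j], lcm[j + 1]
            if je - jb > 1 and xs[je] != xs[jb]:
                c = (je - jb) / (xs[je] - xs[jb])
                for jj in range(jb, je + 1):
                    t = (xs[jj] - xs[jb]) * c - (jj - jb - 1)
                    if max_t < t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t

        dip = max(dip, dip_l, dip_u)
        if low == gcm[ig] and high == lcm[ih]:
            break
        low = gcm[ig]
        high = lcm[ih]

    return dip / (2.0 * n)


def dip_test_calibrated(
    values,
    n_boot: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """(dip, p) with p calibrated by bootstrap from the uniform null.

    ``n_boot`` uniform samples of the observed size give the null dip
    distribution; p is the fraction of null dips at least as large as the
    observed one (add-one correction keeps p > 0).  Samples of fewer than
    10 values are untestable and raise ValueError.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 10:
        raise ValueError("sample too small for the dip test (< 10)")
    d = dip_statistic(x)
    rng = np.random.default_rng(seed)
    null = np.array(
        [dip_statistic(rng.uniform(size=x.size)) for _ in range(n_boot)]
    )
    p = (np.count_nonzero(null >= d) + 1) / (n_boot + 1)
    return d, float(p)
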