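"""Hartigan's dip statistic of unimodality.

The dip of an empirical distribution function F_n is the smallest sup-norm
distance between F_n and any unimodal distribution function; equivalently
twice the dip is the smallest band-width 2d such that some CDF that is
convex up to a mode and concave after fits inside [F_n - d, F_n + d].

This is a direct port of the published algorithm (Hartigan & Hartigan 1985,
Applied Statistics AS 217, with the later corrections circulated with the
reference implementation): iterate computing the greatest convex minorant
and least concave majorant of F_n on a shrinking interval, track the
largest discrepancy, and stop when it no longer improves.

P-values are calibrated by Monte Carlo against the uniform null (the
asymptotically least-favorable unimodal distribution), with the null dip
distribution cached per sample size.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = ["dip_statistic", "dip_test"]


def dip_statistic(values) -> float:
    """Hartigan's dip statistic of a 1-D sample.

    Returns 0.0 for degenerate samples (all values identical).  The minimum
    achievable dip for n distinct points is 1/(2n).
    """
    xs = np.sort(np.asarray(values, dtype=float))
    n = xs.size
    if n < 1:
        raise ValueError("empty sample")
    if n == 1 or xs[0] == xs[-1]:
        return 0.0
    if n in (2, 3):
        return 1.0 / (2.0 * n)

    # 1-based arrays as in the reference implementation.
    x = np.empty(n + 1)
    x[1:] = xs
    mn = np.zeros(n + 1, dtype=np.int64)
    mj = np.zeros(n + 1, dtype=np.int64)
    gcm = np.zeros(n + 2, dtype=np.int64)
    lcm = np.zeros(n + 2, dtype=np.int64)

    # mn[j]: previous touch point of the greatest convex minorant at j.
    mn[1] = 1
    for j in range(2, n + 1):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 1 or (x[j] - x[mnj]) * (mnj - mnmnj) < (x[mnj] - x[mnmnj]) * (
                j - mnj
            ):
                break
            mn[j] = mnmnj

    # mj[k]: next touch point of the least concave majorant at k.
    mj[n] = n
    for k in range(n - 1, 0, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            mjmjk = mj[mjk]
            if mjk == n or (x[k] - x[mjk]) * (mjk - mjmjk) < (x[mjk] - x[mjmjk]) * (
                k - mjk
            ):
                break
            mj[k] = mjmjk

    low, high = 1, n
    dip = 1.0  # in observation-count units; converted to /(2n) at the end

    while True:
        # GCM change points from high down to low.
        gcm[1] = high
        i = 1
        while gcm[i] > low:
            gcm[i + 1] = mn[gcm[i]]
            i += 1
        ig = l_gcm = i
        ix = ig - 1

        # LCM change points from low up to high.
        lcm[1] = low
        i = 1
        while lcm[i] < high:
            lcm[i + 1] = mj[lcm[i]]
            i += 1
        ih = l_lcm = i
        iv = 2

        # Largest distance between the GCM and the LCM on [low, high].
        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            while True:
                gcmix = gcm[ix]
                lcmiv = lcm[iv]
                if gcmix > lcmiv:
                    # next change point comes from the LCM
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (x[lcmiv] - x[gcmi1]) * (
                        gcmix - gcmi1
                    ) / (x[gcmix] - x[gcmi1])
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    # next change point comes from the GCM
                    lcmiv1 = lcm[iv - 1]
                    dx = (x[gcmix] - x[lcmiv1]) * (lcmiv - lcmiv1) / (
                        x[lcmiv] - x[lcmiv1]
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

        # Dip within the current convex-minorant fit.
        dip_l = 0.0
        for j in range(ig, l_gcm):
            max_t = 1.0
            jb = gcm[j + 1]
            je = gcm[j]
            if je - jb > 1 and x[je] != x[jb]:
                C = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (x[jj] - x[jb]) * C
                    if max_t < t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t

        # Dip within the current concave-majorant fit.
        dip_u = 0.0
        for j in range(ih, l_lcm):
            max_t = 1.0
            jb = lcm[j]
            je = lcm[j + 1]
            if je - jb > 1 and x[je] != x[jb]:
                C = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (x[jj] - x[jb]) * C - (jj - jb - 1)
                    if max_t < t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t

        dipnew = max(dip_l, dip_u)
        if dip < dipnew:
            dip = dipnew

        if low == gcm[ig] and high == lcm[ih]:
            break
        low = gcm[ig]
        high = lcm[ih]

    return dip / (2.0 * n)


@lru_cache(maxsize=32)
def _null_table(n: int, n_boot: int, seed: int) -> tuple[float, ...]:
    """Sorted Monte-Carlo null distribution of the dip for sample size n,
    drawn from the uniform distribution."""
    rng = np.random.default_rng(seed)
    return tuple(sorted(dip_statistic(rng.random(n)) for _ in range(n_boot)))


def dip_test(values, n_boot: int = 2000, seed: int = 20230) -> tuple[float, float]:
    """Dip test of unimodality: returns ``(statistic, p_value)``.

    The p-value is the fraction of ``n_boot`` uniform null samples of the
    same size whose dip is at least as large as the observed one (with the
    usual +1 continuity correction).  A degenerate sample (all values
    identical) is treated as unimodal with p = 1.
    """
    xs = np.asarray(values, dtype=float)
    xs = xs[np.isfinite(xs)]
    if xs.size < 4:
        raise ValueError("dip test requires at least 4 finite values")
    stat = dip_statistic(xs)
    if stat == 0.0:
        return 0.0, 1.0
    null = np.asarray(_null_table(xs.size, n_boot, seed))
    exceed = int(np.searchsorted(null, stat, side="left"))
    p = (n_boot - exceed + 1) / (n_boot + 1)
    return stat, float(p)
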