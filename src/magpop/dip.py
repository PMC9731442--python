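"""Hartigan's dip statistic and a bootstrap unimodality test.

The dip of an empirical distribution function F_n is the smallest sup-norm
distance between F_n and the closest unimodal distribution function (convex
below the mode, concave above it, with a jump allowed at the mode).  The
statistic is location/scale invariant, bounded below by 1/(2n), and large
values indicate multimodality.

The computation follows the classical iterative greatest-convex-minorant /
least-concave-majorant algorithm: on a shrinking modal interval, fit the GCM
and LCM to the sorted sample, measure their largest discrepancy, and track
the largest deviation of F_n from either fit outside the candidate modal
interval.  The bootstrap p-value compares the observed dip with dips of
uniform samples of the same size, the standard least-favourable unimodal
null.
"""

from __future__ import annotations

import functools

import numpy as np

__all__ = ["dip_statistic", "dip_test"]


def dip_statistic(values: np.ndarray) -> float:
    """Hartigan's dip statistic of a 1-D sample.

    Parameters
    ----------
    values
        Sample (need not be sorted).  At least one value.

    Returns
    -------
    float
        The dip, in [1/(2n), 0.25].  Degenerate samples (n < 2 or all
        values identical) return the lower bound 1/(2n) capped at 0.25.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 1:
        raise ValueError("dip_statistic requires a nonempty sample")
    if n < 2 or x[0] == x[-1]:
        return min(0.25, 1.0 / (2.0 * n))

    # 1-indexed copy to mirror the published algorithm.
    xs = np.empty(n + 1)
    xs[1:] = x

    # mn[j]: index of the previous support point of the greatest convex
    # minorant fitted to (x_i, i); mj[k]: analogue for the least concave
    # majorant (pool-adjacent-violators style pre-pass).
    mn = np.zeros(n + 1, dtype=np.int64)
    mj = np.zeros(n + 1, dtype=np.int64)
    mn[1] = 1
    for j in range(2, n + 1):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 1 or (xs[j] - xs[mnj]) * (mnj - mnmnj) < (xs[mnj] - xs[mnmnj]) * (j - mnj):
                break
            mn[j] = mnmnj
    mj[n] = n
    for k in range(n - 1, 0, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            mjmjk = mj[mjk]
            if mjk == n or (xs[k] - xs[mjk]) * (mjk - mjmjk) < (xs[mjk] - xs[mjmjk]) * (k - mjk):
                break
            mj[k] = mjmjk

    low, high = 1, n
    dip = 1.0  # in units of counts; divided by 2n at the end
    gcm = np.zeros(n + 2, dtype=np.int64)
    lcm = np.zeros(n + 2, dtype=np.int64)

    while True:
        # Support points of the GCM on [low, high], collected from the top,
        # and of the LCM, collected from the bottom.
        gcm[1] = high
        i = 1
        while gcm[i] > low:
            gcm[i + 1] = mn[gcm[i]]
            i += 1
        ig = l_gcm = i
        ix = ig - 1

        lcm[1] = low
        i = 1
        while lcm[i] < high:
            lcm[i + 1] = mj[lcm[i]]
            i += 1
        ih = l_lcm = i
        iv = 2

        # Largest distance between the two fits over the current interval.
        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            while True:
                gcmix = gcm[ix]
                lcmiv = lcm[iv]
                if gcmix > lcmiv:
                    # probe LCM point against the GCM segment
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (xs[lcmiv] - xs[gcmi1]) * (gcmix - gcmi1) / (
                        xs[gcmix] - xs[gcmi1]
                    )
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    # probe GCM point against the LCM segment
                    lcmiv1 = lcm[iv - 1]
                    dx = (xs[gcmix] - xs[lcmiv1]) * (lcmiv - lcmiv1) / (xs[lcmiv] - xs[lcmiv1]) - (
                        gcmix - lcmiv1 - 1
                    )
                    ix -= 1
                    if dx >= d:
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

        # Largest deviation of F_n from the GCM left of the modal interval.
        dip_l = 0.0
        for j in range(ig, l_gcm):
            jb = gcm[j + 1]
            je = gcm[j]
            max_t = 1.0
            if je - jb > 1 and xs[je] != xs[jb]:
                c = (je - jb) / (xs[je] - xs[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (xs[jj] - xs[jb]) * c
                    if max_t < t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t

        # Largest deviation of F_n from the LCM right of the modal interval.
        dip_u = 0.0
        for j in range(ih, l_lcm):
            jb = lcm[j]
            je = lcm[j + 1]
            max_t = 1.0
            if je - jb > 1 and xs[je] != xs[jb]:
                c = (je - jb) / (xs[je] - xs[jb])
                for jj in range(jb, je + 1):
                    t = (xs[jj] - xs[jb]) * c - (jj - jb - 1)
                    if max_t < t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t

        new_dip = max(dip_l, dip_u)
        if dip < new_dip:
            dip = new_dip
        if low == gcm[ig] and high == lcm[ih]:
            break
        low = gcm[ig]
        high = lcm[ih]

    return dip / (2.0 * n)


@functools.lru_cache(maxsize=64)
def _null_dips(n: int, n_boot: int, seed: int) -> tuple:
    """Bootstrap null dips for samples of size n drawn from Uniform(0,1)."""
    rng = np.random.default_rng(seed)
    return tuple(dip_statistic(rng.random(n)) for _ in range(n_boot))


def dip_test(
    values: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    max_n: int = 1000,
) -> tuple[float, float]:
    """Dip statistic plus a bootstrap p-value against the uniform null.

    Samples larger than ``max_n`` are deterministically subsampled before
    testing so that the bootstrap stays cheap; the dip is scale invariant so
    subsampling only costs power.

    Returns
    -------
    (statistic, p_value)
        ``p = (1 + #{dip_boot >= dip_obs}) / (n_boot + 1)``.
    """
    values = np.asarray(values, dtype=float)
    if values.size > max_n:
        rng = np.random.default_rng(seed + 1)
        values = rng.choice(values, size=max_n, replace=False)
    stat = dip_statistic(values)
    null = np.array(_null_dips(values.size, n_boot, seed))
    p = (1.0 + np.sum(null >= stat)) / (n_boot + 1.0)
    return float(stat), float(p)
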