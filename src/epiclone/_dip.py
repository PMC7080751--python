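"""Hartigan's dip statistic of unimodality.

The dip of an empirical distribution function F_n is the smallest sup-norm
distance between F_n and any unimodal distribution function (convex below its
mode, concave above).  It is computed by the classic modal-interval iteration:
repeatedly fit the greatest convex minorant (GCM) and least concave majorant
(LCM) of F_n on the current interval, measure their largest vertical gap,
fold the deviations outside the candidate modal interval into the running
dip, and shrink the interval — bookkeeping follows the published algorithm
(Hartigan & Hartigan 1985, AS 217), working in step units of 1/n with the
final statistic halved.

Correctness is pinned down in the test suite by an independent linear-
programming oracle that minimises the sup-norm over piecewise-linear unimodal
distribution functions directly.
"""

from __future__ import annotations

import numpy as np


def dip_statistic(values) -> float:
    """Dip statistic of a 1-d sample (any order; ties allowed)."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("dip_statistic needs at least one value")
    if n == 1 or x[0] == x[-1]:
        return 0.0
    if n <= 3:
        return 1.0 / (2.0 * n)

    # 1-based arrays, masses are the indices 1..n
    xx = np.empty(n + 1)
    xx[1:] = x
    mn = np.zeros(n + 1, dtype=np.int64)
    mj = np.zeros(n + 1, dtype=np.int64)
    gcm = np.zeros(n + 2, dtype=np.int64)
    lcm = np.zeros(n + 2, dtype=np.int64)

    low, high = 1, n
    dip = 1.0  # in index (step) units; converted to probability at the end

    while True:
        # -- greatest convex minorant pointers on [low, high] --------------
        mn[low] = low
        for i in range(low + 1, high + 1):
            mn[i] = i - 1
            while True:
                mnj = mn[i]
                if mnj == low:
                    break
                mnmnj = mn[mnj]
                if (xx[i] - xx[mnj]) * (mnj - mnmnj) < (xx[mnj] - xx[mnmnj]) * (i - mnj):
                    break
                mn[i] = mnmnj
        # -- least concave majorant pointers -------------------------------
        mj[high] = high
        for i in range(high - 1, low - 1, -1):
            mj[i] = i + 1
            while True:
                mjk = mj[i]
                if mjk == high:
                    break
                mjmjk = mj[mjk]
                if (xx[i] - xx[mjk]) * (mjk - mjmjk) < (xx[mjk] - xx[mjmjk]) * (i - mjk):
                    break
                mj[i] = mjmjk

        # vertex lists: gcm runs high -> low, lcm runs low -> high
        gcm[1] = high
        k = 1
        while gcm[k] > low:
            gcm[k + 1] = mn[gcm[k]]
            k += 1
        l_gcm = k
        lcm[1] = low
        k = 1
        while lcm[k] < high:
            lcm[k + 1] = mj[lcm[k]]
            k += 1
        l_lcm = k

        ig, ih = l_gcm, l_lcm
        # -- largest gap between the GCM and LCM ---------------------------
        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            ix, iv = l_gcm - 1, 2
            while True:
                gcmix, lcmiv = gcm[ix], lcm[iv]
                if gcmix > lcmiv:
                    # gap at the LCM vertex, against the spanning GCM chord
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (xx[lcmiv] - xx[gcmi1]) * (
                        gcmix - gcmi1
                    ) / (xx[gcmix] - xx[gcmi1])
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig, ih = ix + 1, iv - 1
                else:
                    # gap at the GCM vertex, against the spanning LCM chord
                    lcmiv1 = lcm[iv - 1]
                    dx = (xx[gcmix] - xx[lcmiv1]) * (lcmiv - lcmiv1) / (
                        xx[lcmiv] - xx[lcmiv1]
                    ) - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx >= d:
                        d = dx
                        ig, ih = ix + 1, iv
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

        # -- deviations of F_n from the hulls outside the modal interval ---
        dip_l = 0.0
        for j in range(ig, l_gcm):
            max_t = 1.0
            jb, je = gcm[j + 1], gcm[j]
            if je - jb > 1 and xx[je] != xx[jb]:
                c = (je - jb) / (xx[je] - xx[jb])
                for i in range(jb + 1, je):
                    t = (i - jb + 1) - (xx[i] - xx[jb]) * c
                    if max_t < t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t

        dip_u = 0.0
        for j in range(ih, l_lcm):
            max_t = 1.0
            jb, je = lcm[j], lcm[j + 1]
            if je - jb > 1 and xx[je] != xx[jb]:
                c = (je - jb) / (xx[je] - xx[jb])
                for i in range(jb + 1, je):
                    t = (xx[i] - xx[jb]) * c - (i - jb - 1)
                    if max_t < t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t

        dipnew = dip_l if dip_l > dip_u else dip_u
        if dip < dipnew:
            dip = dipnew

        new_low, new_high = gcm[ig], lcm[ih]
        if new_low == low and new_high == high:
            break
        low, high = int(new_low), int(new_high)

    return dip / (2.0 * n)
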