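"""Compiled hot loop for the whole-dataset EHH/iHH scan.

Identical semantics to the pure-numpy path in :mod:`sweepscan.selstats`
(group refinement marker-by-marker, missing alleles isolate a haplotype
permanently, trapezoidal integration of max(EHH - cutoff, 0) over cM);
the equivalence is asserted by tests.  Falls back transparently when numba
is unavailable.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _side_area(H, codes, pos_bp, pos_cm, carriers, focal, step, cutoff, max_gap):
    """(area, truncated) for one allele class on one side of the focal SNP."""
    n = carriers.shape[0]
    npairs = n * (n - 1) // 2
    nvar = H.shape[1]
    labels = np.zeros(n, dtype=np.int64)
    dead = np.zeros(n, dtype=np.uint8)
    key = np.empty(n, dtype=np.int64)
    newlab = np.empty(n, dtype=np.int64)
    counts = np.empty(n, dtype=np.int64)
    area = 0.0
    prev_cm = pos_cm[focal]
    prev_e = 1.0
    truncated = False
    j = focal
    while True:
        jn = j + step
        if jn < 0 or jn >= nvar or codes[jn] != codes[focal]:
            truncated = True
            break
        gap = pos_bp[jn] - pos_bp[j]
        if gap < 0:
            gap = -gap
        if gap > max_gap:
            truncated = True
            break
        for i in range(n):
            a = H[carriers[i], jn]
            if a < 0:
                dead[i] = 1
            if dead[i]:
                key[i] = 4 * n + i  # permanently unique
            else:
                key[i] = labels[i] * 4 + a
        # O(n^2) relabel to consecutive group ids
        g = 0
        for i in range(n):
            newlab[i] = -1
        for i in range(n):
            if newlab[i] >= 0:
                continue
            newlab[i] = g
            for k in range(i + 1, n):
                if newlab[k] < 0 and key[k] == key[i]:
                    newlab[k] = g
            g += 1
        hom = 0
        for gi in range(g):
            counts[gi] = 0
        for i in range(n):
            labels[i] = newlab[i]
            counts[newlab[i]] += 1
        for gi in range(g):
            hom += counts[gi] * (counts[gi] - 1)
        e = hom / (2.0 * npairs)
        cm = pos_cm[jn]
        y0 = prev_e - cutoff
        if y0 < 0.0:
            y0 = 0.0
        y1 = e - cutoff
        if y1 < 0.0:
            y1 = 0.0
        dx = cm - prev_cm
        if dx < 0.0:
            dx = -dx
        area += 0.5 * (y0 + y1) * dx
        prev_cm = cm
        prev_e = e
        j = jn
        if e < cutoff:
            break
    return area, truncated


@njit(cache=True)
def scan_ihh(H, codes, pos_bp, pos_cm, eligible, cutoff, max_gap):
    """iHH for every eligible SNP.

    Returns (ihh_a, ihh_d, status) with status 0 = ok, 1 = too few
    carriers of one allele, 2 = curve truncated (edge or gap).
    """
    nh, nvar = H.shape
    ihh_a = np.full(nvar, np.nan)
    ihh_d = np.full(nvar, np.nan)
    status = np.zeros(nvar, dtype=np.int8)
    anc = np.empty(nh, dtype=np.int64)
    der = np.empty(nh, dtype=np.int64)
    for j in range(nvar):
        if not eligible[j]:
            continue
        na = 0
        nd = 0
        for i in range(nh):
            a = H[i, j]
            if a == 0:
                anc[na] = i
                na += 1
            elif a == 1:
                der[nd] = i
                nd += 1
        if na < 2 or nd < 2:
            status[j] = 1
            continue
        a_l, t1 = _side_area(H, codes, pos_bp, pos_cm, anc[:na], j, -1, cutoff, max_gap)
        a_r, t2 = _side_area(H, codes, pos_bp, pos_cm, anc[:na], j, 1, cutoff, max_gap)
        d_l, t3 = _side_area(H, codes, pos_bp, pos_cm, der[:nd], j, -1, cutoff, max_gap)
        d_r, t4 = _side_area(H, codes, pos_bp, pos_cm, der[:nd], j, 1, cutoff, max_gap)
        ihh_a[j] = a_l + a_r
        ihh_d[j] = d_l + d_r
        if t1 or t2 or t3 or t4:
            status[j] = 2
    return ihh_a, ihh_d, status
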