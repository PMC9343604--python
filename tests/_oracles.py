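"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's algorithms: EHH by explicit
pairwise haplotype comparison, the differentiation LRT by dense grid search
over the ancestral frequency, and empirical P-values by naive counting.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from sweepscan.selstats import EPS_MU, VAR_FLOOR


def brute_ehh(h: np.ndarray, carriers: np.ndarray, focal: int, upto: int) -> float:
    """EHH between ``focal`` and ``upto`` (inclusive) by pairwise identity.

    A pair counts as homozygous iff both haplotypes are non-missing and
    equal at every SNP in the interval.
    """
    lo, hi = min(focal, upto), max(focal, upto)
    sub = h[np.asarray(carriers)][:, lo : hi + 1]
    n = sub.shape[0]
    ident = 0
    pairs = 0
    for i, j in combinations(range(n), 2):
        pairs += 1
        a, b = sub[i], sub[j]
        if np.all((a == b) & (a >= 0)):
            ident += 1
    return ident / pairs


def grid_lrt(
    freqs, sizes, c, tested: int = 0, step: float = 1e-4
) -> float:
    """Differentiation LRT by dense grid search over mu (same model terms
    as the implementation: Normal drift + sampling variance, floored)."""
    x = np.asarray(freqs, dtype=float)
    n = np.asarray(sizes, dtype=float)
    c = np.asarray(c, dtype=float)
    mu = np.arange(step, 1.0, step)
    mu = np.clip(mu, EPS_MU, 1 - EPS_MU)

    def nll(idx):
        tot = np.zeros(mu.shape)
        for i in idx:
            v = np.maximum(c[i] * mu * (1 - mu) + mu * (1 - mu) / n[i], VAR_FLOOR)
            tot += 0.5 * np.log(2 * np.pi * v) + (x[i] - mu) ** 2 / (2 * v)
        return tot.min()

    keep = [i for i in range(3) if i != tested]
    v_t = max((c[tested] + 1.0 / n[tested]) * x[tested] * (1 - x[tested]), VAR_FLOOR)
    drop = -0.5 * np.log(2 * np.pi * v_t)
    lrt = 2.0 * ((-nll(keep) + drop) - (-nll(range(3))))
    return max(lrt, 0.0)


def naive_empirical_p(value: float, background) -> float:
    bg = [b for b in background if np.isfinite(b)]
    r = sum(1 for b in bg if b >= value)
    return (1 + r) / (1 + len(bg))
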