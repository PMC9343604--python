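"""Per-SNP selection statistics.

Two complementary signals of a recent hard sweep:

* **Extended haplotype homozygosity.** EHH(x) is the probability that two
  randomly drawn haplotypes carrying a given allele at a focal SNP are
  identical at every SNP between the focal SNP and x.  Integrating the EHH
  curve over genetic distance separately for ancestral- and derived-allele
  carriers gives iHH_A and iHH_D; the integrated haplotype score is
  ln(iHH_A / iHH_D), standardized within derived-allele-frequency bins so
  that scores are comparable across frequencies.  A strongly negative raw
  score (long derived haplotypes) marks an ongoing/recent sweep of the
  derived allele.

* **Three-population differentiation LRT.**  On a star tree relating a
  target and two reference populations, each observed allele frequency x_i
  is modelled as Normal(mu, c_i * mu(1-mu) + mu(1-mu)/n_i): Balding-Nichols
  drift variance plus binomial sampling noise, with branch drift c_i fitted
  genome-wide from pairwise Hudson Fst by additivity.  The test drops the
  target branch from the likelihood (its frequency unconstrained, the
  dropped density evaluated at its maximum) and reports
  LRT = 2 (lnL_alt - lnL_null) >= 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from . import _ehh_kernel as _kernel
from .hapio import GeneticMap, HaplotypeMatrix

EPS_MU = 1e-6
VAR_FLOOR = 1e-6

# per-SNP status flags used by the iHS scan
FLAG_OK = "ok"
FLAG_UNPOLARIZED = "unpolarized"
FLAG_INELIGIBLE_FREQ = "ineligible_freq"
FLAG_TOO_FEW_CARRIERS = "too_few_carriers"
FLAG_TRUNCATED = "truncated"
FLAG_ZERO_IHH = "zero_ihh"


class EhhUndefinedError(ValueError):
    """EHH is undefined (fewer than two carrier haplotypes)."""


@dataclass
class EhhCurve:
    """EHH decay around one focal SNP for one allele class.

    ``left_*``/``right_*`` run from the focal SNP outward (the focal point,
    EHH = 1, is the first element on each side).  A side is ``truncated``
    when the curve hit the chromosome edge or an inter-marker gap larger
    than ``max_gap_bp`` before decaying below ``cutoff``.
    """

    focal_index: int
    allele: str  # "ancestral" | "derived"
    n_carriers: int
    cutoff: float
    left_cm: np.ndarray
    left_ehh: np.ndarray
    right_cm: np.ndarray
    right_ehh: np.ndarray
    left_truncated: bool
    right_truncated: bool

    @property
    def truncated(self) -> bool:
        return self.left_truncated or self.right_truncated


def _extend_side(
    hap_cols: np.ndarray,
    chrom_codes: np.ndarray,
    pos_bp: np.ndarray,
    pos_cm: np.ndarray,
    carriers: np.ndarray,
    focal: int,
    step: int,
    cutoff: float,
    max_gap_bp: int,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """March marker-by-marker on one side, refining haplotype groups.

    Haplotypes identical so far share a group label; EHH is the homozygous
    pair fraction sum_g C(k_g,2) / C(n,2).  A missing allele permanently
    isolates its haplotype (conservative: never homozygous with anyone past
    that point).
    """
    n = carriers.size
    npairs = n * (n - 1) // 2
    labels = np.zeros(n, dtype=np.int64)
    cms = [pos_cm[focal]]
    ehhs = [1.0]
    truncated = False
    m = hap_cols.shape[1]
    j = focal
    while True:
        jn = j + step
        if jn < 0 or jn >= m or chrom_codes[jn] != chrom_codes[focal]:
            truncated = True  # chromosome edge before decaying below cutoff
            break
        if abs(int(pos_bp[jn]) - int(pos_bp[j])) > max_gap_bp:
            truncated = True
            break
        a = hap_cols[carriers, jn].astype(np.int64)
        key = labels * 3 + np.where(a < 0, 2, a)
        miss = a < 0
        if miss.any():
            # unique keys >= 3n so a missing haplotype becomes (and stays) a singleton
            key[miss] = 3 * n + np.flatnonzero(miss)
        _, labels = np.unique(key, return_inverse=True)
        counts = np.bincount(labels)
        e = float((counts * (counts - 1)).sum()) / (2 * npairs)
        cms.append(pos_cm[jn])
        ehhs.append(e)
        j = jn
        if e < cutoff:
            break
    return np.asarray(cms, dtype=float), np.asarray(ehhs, dtype=float), truncated


def compute_ehh(
    hap: HaplotypeMatrix,
    focal_index: int,
    allele: str,
    gmap: GeneticMap | None = None,
    ehh_cutoff: float = 0.05,
    max_gap_bp: int = 200_000,
    _precomputed_cm: np.ndarray | None = None,
) -> EhhCurve:
    """EHH curve around ``focal_index`` among carriers of ``allele``.

    Without a genetic map, physical distance stands in for genetic distance
    at 1 cM/Mb.
    """
    if allele not in ("ancestral", "derived"):
        raise ValueError("allele must be 'ancestral' or 'derived'")
    h = hap.haplotypes
    target = 1 if allele == "derived" else 0
    carriers = np.flatnonzero(h[:, focal_index] == target)
    if carriers.size < 2:
        raise EhhUndefinedError(
            f"<2 {allele} carriers at variant index {focal_index}"
        )
    chroms = hap.variants["chrom"]
    codes = pd.factorize(chroms, sort=False)[0]
    pos_bp = hap.variants["pos_bp"].to_numpy()
    if _precomputed_cm is not None:
        pos_cm = _precomputed_cm
    elif gmap is not None:
        pos_cm = np.empty(len(pos_bp))
        for chrom in pd.unique(chroms):
            mask = chroms.to_numpy() == chrom
            pos_cm[mask] = gmap.interpolate(str(chrom), pos_bp[mask])
    else:
        pos_cm = pos_bp / 1e6  # 1 cM/Mb surrogate

    lcm, lehh, ltr = _extend_side(
        h, codes, pos_bp, pos_cm, carriers, focal_index, -1, ehh_cutoff, max_gap_bp
    )
    rcm, rehh, rtr = _extend_side(
        h, codes, pos_bp, pos_cm, carriers, focal_index, +1, ehh_cutoff, max_gap_bp
    )
    return EhhCurve(
        focal_index=focal_index,
        allele=allele,
        n_carriers=int(carriers.size),
        cutoff=ehh_cutoff,
        left_cm=lcm,
        left_ehh=lehh,
        right_cm=rcm,
        right_ehh=rehh,
        left_truncated=ltr,
        right_truncated=rtr,
    )


def integrate_ihh(curve: EhhCurve) -> float:
    """Trapezoidal area of max(EHH - cutoff, 0) over genetic distance, both
    sides summed (cM units)."""
    total = 0.0
    focal_cm = curve.left_cm[0]
    for cms, ehhs in ((curve.left_cm, curve.left_ehh), (curve.right_cm, curve.right_ehh)):
        if cms.size < 2:
            continue
        x = np.abs(cms - focal_cm)
        y = np.clip(ehhs - curve.cutoff, 0.0, None)
        total += float(np.trapezoid(y, x))
    return total


def ihs_raw(ihh_a: float, ihh_d: float) -> float:
    """Unstandardized integrated haplotype score ln(iHH_A / iHH_D)."""
    if not (ihh_a > 0 and ihh_d > 0):
        raise ValueError("ihs_raw requires ihh_a > 0 and ihh_d > 0")
    return float(np.log(ihh_a / ihh_d))


def standardize_ihs(
    scores: np.ndarray, derived_freq: np.ndarray, bin_width: float = 0.025
) -> np.ndarray:
    """Standardize raw scores within derived-allele-frequency bins.

    Within each bin of width ``bin_width`` the bin mean is subtracted and
    the bin population-SD (ddof=0) divides; bins with fewer than two defined
    scores or zero SD yield NaN.
    """
    scores = np.asarray(scores, dtype=float)
    freq = np.asarray(derived_freq, dtype=float)
    out = np.full(scores.shape, np.nan)
    defined = np.isfinite(scores) & np.isfinite(freq)
    if not defined.any():
        return out
    bins = np.floor(freq[defined] / bin_width).astype(np.int64)
    vals = scores[defined]
    idx = np.flatnonzero(defined)
    for b in np.unique(bins):
        sel = bins == b
        if sel.sum() < 2:
            continue
        v = vals[sel]
        sd = v.std(ddof=0)
        if sd == 0:
            continue
        out[idx[sel]] = (v - v.mean()) / sd
    return out


# ---------------------------------------------------------------------------
# Hudson Fst
# ---------------------------------------------------------------------------

def hudson_fst(p1, n1, p2, n2) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP Hudson Fst components (numerator, denominator).

    ``n1``/``n2`` are sampled allele (haplotype) counts, >= 2.  The
    genome-wide estimate is the ratio of sums (ratio of averages), which is
    robust to low-frequency variants.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ValueError("hudson_fst requires allele counts >= 2")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def genome_fst(num: np.ndarray, den: np.ndarray) -> float:
    """Ratio-of-sums genome-wide Fst; SNPs with zero denominator are skipped."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    keep = np.isfinite(num) & np.isfinite(den) & (den != 0)
    if not keep.any():
        raise ValueError("no SNPs with non-zero Fst denominator")
    return float(num[keep].sum() / den[keep].sum())


# ---------------------------------------------------------------------------
# Drift tree + differentiation LRT
# ---------------------------------------------------------------------------

@dataclass
class DriftTree:
    """Star-tree branch drift parameters for (target, ref_SA, ref_global)."""

    populations: tuple[str, str, str]
    c: np.ndarray  # (3,) nonnegative branch drift parameters
    fst_pairs: dict[str, float] = field(default_factory=dict)
    clamped: bool = False

    @property
    def c_target(self) -> float:
        return float(self.c[0])


def estimate_drift_tree(
    fst_t_r1: float,
    fst_t_r2: float,
    fst_r1_r2: float,
    populations: tuple[str, str, str] = ("target", "ref_sa", "ref_global"),
    floor: float = 1e-6,
) -> DriftTree:
    """Additive branch lengths from the three pairwise genome-wide Fst.

    c_i + c_j = Fst(i, j); negative solutions (non-tree-like geometry) are
    clamped to ``floor`` with a warning.
    """
    c_t = (fst_t_r1 + fst_t_r2 - fst_r1_r2) / 2.0
    c_1 = (fst_t_r1 + fst_r1_r2 - fst_t_r2) / 2.0
    c_2 = (fst_t_r2 + fst_r1_r2 - fst_t_r1) / 2.0
    c = np.array([c_t, c_1, c_2], dtype=float)
    clamped = bool(np.any(c < floor))
    if clamped:
        warnings.warn(
            "additive drift solution had a branch below the floor; clamped",
            stacklevel=2,
        )
        c = np.maximum(c, floor)
    return DriftTree(
        populations=populations,
        c=c,
        fst_pairs={
            f"{populations[0]}~{populations[1]}": float(fst_t_r1),
            f"{populations[0]}~{populations[2]}": float(fst_t_r2),
            f"{populations[1]}~{populations[2]}": float(fst_r1_r2),
        },
        clamped=clamped,
    )


def _neg_loglik(mu, x, c, n):
    """Negative log-likelihood of frequencies x under drift+sampling Normal.

    ``mu`` may be scalar or an array broadcast against SNP-shaped ``x``
    terms; variances are floored at VAR_FLOOR.
    """
    v = c * mu * (1 - mu) + mu * (1 - mu) / n
    v = np.maximum(v, VAR_FLOOR)
    return 0.5 * np.log(2 * np.pi * v) + (x - mu) ** 2 / (2 * v)


def _drop_term_loglik(x, c, n):
    """Log-density of the dropped branch at its own maximum (evaluated at x)."""
    v = np.maximum((c + 1.0 / n) * x * (1 - x), VAR_FLOOR)
    return -0.5 * np.log(2 * np.pi * v)


def treeselect_lrt(
    freqs: tuple[float, float, float],
    sizes: tuple[float, float, float],
    tree: DriftTree,
    tested_branch: int = 0,
) -> float:
    """Differentiation LRT for one SNP (scalar reference implementation).

    Null: a single ancestral frequency mu generates all three observed
    frequencies through branch drift + sampling noise.  Alternative: the
    tested branch is released (its term evaluated at maximal density) and mu
    is refitted on the remaining two populations.
    """
    x = np.asarray(freqs, dtype=float)
    n = np.asarray(sizes, dtype=float)
    c = np.asarray(tree.c, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    keep = np.ones(3, dtype=bool)
    keep[tested_branch] = False

    def null_obj(mu):
        return float(np.sum(_neg_loglik(mu, x, c, n)))

    def alt_obj(mu):
        return float(np.sum(_neg_loglik(mu, x[keep], c[keep], n[keep])))

    lo, hi = EPS_MU, 1 - EPS_MU
    # coarse grid bracket guards against any multimodality, then refine
    grid = np.linspace(lo, hi, 201)

    def _minimize(obj):
        vals = np.array([obj(g) for g in grid])
        k = int(np.argmin(vals))
        a = grid[max(k - 1, 0)]
        b = grid[min(k + 1, grid.size - 1)]
        res = minimize_scalar(obj, bounds=(a, b), method="bounded", options={"xatol": 1e-10})
        if not res.success:
            raise RuntimeError("mu optimization failed to converge")
        return float(res.fun)

    nll_null = _minimize(null_obj)
    nll_alt = _minimize(alt_obj)
    lnl_drop = float(_drop_term_loglik(x[tested_branch], c[tested_branch], n[tested_branch]))
    lrt = 2.0 * ((-nll_alt + lnl_drop) - (-nll_null))
    return max(lrt, 0.0)


def treeselect_lrt_batch(
    freqs: np.ndarray,
    sizes: np.ndarray,
    tree: DriftTree,
    tested_branch: int = 0,
    refine_iters: int = 70,
) -> np.ndarray:
    """Vectorized LRT over many SNPs.

    ``freqs``/``sizes`` have shape (n_snps, 3) ordered as the tree's
    populations.  A 201-point coarse grid locates the likelihood optimum per
    SNP and golden-section refines it; agrees with :func:`treeselect_lrt`
    to well below 1e-3.
    """
    x = np.asarray(freqs, dtype=float)
    n = np.asarray(sizes, dtype=float)
    c = np.asarray(tree.c, dtype=float)
    keep = np.ones(3, dtype=bool)
    keep[tested_branch] = False

    def total_nll(mu, xs, cs, ns):
        # mu: (n_snps,), xs: (n_snps, k)
        out = np.zeros(mu.shape)
        for j in range(xs.shape[1]):
            out += _neg_loglik(mu, xs[:, j], cs[j], ns[:, j])
        return out

    def _vector_minimize(xs, cs, ns):
        grid = np.linspace(EPS_MU, 1 - EPS_MU, 201)
        vals = np.stack([total_nll(np.full(xs.shape[0], g), xs, cs, ns) for g in grid])
        kbest = np.argmin(vals, axis=0)
        a = grid[np.maximum(kbest - 1, 0)]
        b = grid[np.minimum(kbest + 1, grid.size - 1)]
        invphi = (np.sqrt(5.0) - 1) / 2
        x1 = b - invphi * (b - a)
        x2 = a + invphi * (b - a)
        f1 = total_nll(x1, xs, cs, ns)
        f2 = total_nll(x2, xs, cs, ns)
        for _ in range(refine_iters):
            take1 = f1 < f2
            b = np.where(take1, x2, b)
            a = np.where(take1, a, x1)
            x1n = np.where(take1, b - invphi * (b - a), x2)
            x2n = np.where(take1, x1, a + invphi * (b - a))
            fnew = total_nll(np.where(take1, x1n, x2n), xs, cs, ns)
            f1, f2 = np.where(take1, fnew, f2), np.where(take1, f1, fnew)
            x1, x2 = x1n, x2n
        mu = np.where(f1 < f2, x1, x2)
        return total_nll(mu, xs, cs, ns)

    nll_null = _vector_minimize(x, c, n)
    nll_alt = _vector_minimize(x[:, keep], c[keep], n[:, keep])
    lnl_drop = _drop_term_loglik(x[:, tested_branch], c[tested_branch], n[:, tested_branch])
    lrt = 2.0 * ((-nll_alt + lnl_drop) - (-nll_null))
    return np.maximum(lrt, 0.0)


# ---------------------------------------------------------------------------
# Whole-dataset scans
# ---------------------------------------------------------------------------

def ihs_scan(
    hap: HaplotypeMatrix,
    gmap: GeneticMap | None = None,
    ehh_cutoff: float = 0.05,
    max_gap_bp: int = 200_000,
    freq_range: tuple[float, float] = (0.05, 0.95),
    bin_width: float = 0.025,
    keep_truncated: bool = False,
) -> pd.DataFrame:
    """iHS for every eligible SNP of the target population.

    Eligibility: polarizable, derived frequency inside ``freq_range``, and
    at least two carriers of each allele.  Curves truncated by a chromosome
    edge or an over-``max_gap_bp`` inter-marker gap are excluded unless
    ``keep_truncated``; SNPs with a zero integral on either side carry no
    score.  Returns one row per variant with a status flag.
    """
    nvar = hap.n_variants
    freq = hap.derived_freq()
    pol = hap.variants["polarizable"].to_numpy(dtype=bool)
    chroms = hap.variants["chrom"]
    pos_bp = hap.variants["pos_bp"].to_numpy()
    if gmap is not None:
        pos_cm = np.empty(nvar)
        arr = chroms.to_numpy()
        for chrom in pd.unique(chroms):
            mask = arr == chrom
            pos_cm[mask] = gmap.interpolate(str(chrom), pos_bp[mask])
    else:
        pos_cm = pos_bp / 1e6

    ihh_a = np.full(nvar, np.nan)
    ihh_d = np.full(nvar, np.nan)
    raw = np.full(nvar, np.nan)
    flags = np.full(nvar, FLAG_OK, dtype=object)

    h = np.ascontiguousarray(hap.haplotypes)
    codes = np.ascontiguousarray(pd.factorize(chroms, sort=False)[0], dtype=np.int64)
    lo, hi = freq_range
    eligible = pol & np.isfinite(freq) & (freq >= lo) & (freq <= hi)
    flags[~pol] = FLAG_UNPOLARIZED
    flags[pol & ~eligible] = FLAG_INELIGIBLE_FREQ

    if _kernel.HAVE_NUMBA:
        ka, kd, status = _kernel.scan_ihh(
            h,
            codes,
            np.ascontiguousarray(pos_bp, dtype=np.int64),
            np.ascontiguousarray(pos_cm, dtype=np.float64),
            np.ascontiguousarray(eligible, dtype=np.bool_),
            float(ehh_cutoff),
            int(max_gap_bp),
        )
    else:  # pure-numpy fallback, same semantics
        ka = np.full(nvar, np.nan)
        kd = np.full(nvar, np.nan)
        status = np.zeros(nvar, dtype=np.int8)
        for j in np.flatnonzero(eligible):
            col = h[:, j]
            carriers_d = np.flatnonzero(col == 1)
            carriers_a = np.flatnonzero(col == 0)
            if carriers_d.size < 2 or carriers_a.size < 2:
                status[j] = 1
                continue
            areas = []
            truncated = False
            for carriers in (carriers_a, carriers_d):
                area = 0.0
                for step in (-1, +1):
                    cms, ehhs, tr = _extend_side(
                        h, codes, pos_bp, pos_cm, carriers, j, step,
                        ehh_cutoff, max_gap_bp,
                    )
                    truncated = truncated or tr
                    if cms.size >= 2:
                        x = np.abs(cms - cms[0])
                        y = np.clip(ehhs - ehh_cutoff, 0.0, None)
                        area += float(np.trapezoid(y, x))
                areas.append(area)
            ka[j], kd[j] = areas
            if truncated:
                status[j] = 2

    for j in np.flatnonzero(eligible):
        if status[j] == 1:
            flags[j] = FLAG_TOO_FEW_CARRIERS
            continue
        if status[j] == 2 and not keep_truncated:
            flags[j] = FLAG_TRUNCATED
            continue
        ia, idd = ka[j], kd[j]
        ihh_a[j] = ia
        ihh_d[j] = idd
        if ia > 0 and idd > 0:
            raw[j] = np.log(ia / idd)
        else:
            flags[j] = FLAG_ZERO_IHH

    std = standardize_ihs(raw, freq, bin_width=bin_width)
    return pd.DataFrame(
        {
            "chrom": chroms.to_numpy(),
            "pos_bp": pos_bp,
            "variant_id": hap.variants["variant_id"].to_numpy(),
            "derived_freq": freq,
            "ihh_a": ihh_a,
            "ihh_d": ihh_d,
            "ihs_raw": raw,
            "ihs_std": std,
            "flag": flags,
        }
    )


def lrt_scan(
    haps: dict[str, HaplotypeMatrix],
    target: str,
    ref_sa: str,
    ref_global: str,
) -> tuple[np.ndarray, DriftTree]:
    """Differentiation LRT for every SNP of one (target, ref_SA, ref_global)
    comparison; the drift tree is fitted from genome-wide Hudson Fst first.

    Populations must already carry identical variant sets
    (see :func:`sweepscan.hapio.intersect_variants`).
    """
    order = (target, ref_sa, ref_global)
    freqs = np.column_stack([haps[k].derived_freq() for k in order])
    sizes = np.column_stack(
        [np.maximum(haps[k].called_allele_count(), 2) for k in order]
    )
    fsts = {}
    for i, j in ((0, 1), (0, 2), (1, 2)):
        num, den = hudson_fst(freqs[:, i], sizes[:, i], freqs[:, j], sizes[:, j])
        fsts[(i, j)] = genome_fst(num, den)
    tree = estimate_drift_tree(
        fsts[(0, 1)], fsts[(0, 2)], fsts[(1, 2)], populations=order
    )
    lrt = treeselect_lrt_batch(freqs, sizes, tree, tested_branch=0)
    return lrt, tree
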