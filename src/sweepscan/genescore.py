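"""Gene-level aggregation, empirical background P-values, and the combined
Fisher score.

Per-SNP |iHS| and LRT scores are summarized per gene (mean or median), each
summary is ranked against the gene-level background distribution to give an
empirical right-tail P-value with the (r+1)/(n+1) correction, and the two
P-values are merged with Fisher's combination statistic

    Z_F = -2 (ln P_|iHS| + ln P_LRT),    Z_F ~ chi-square(4 df) under the null,

whose survival function gives the gene's formal P-value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2

GENE_SCORE_COLUMNS = [
    "gene_id",
    "comparison",
    "statistic",
    "n_snps",
    "n_ihs",
    "n_lrt",
    "s_ihs",
    "s_lrt",
    "p_ihs",
    "p_lrt",
    "z_f",
    "p_zf",
]


def assign_snps_to_genes(
    variants: pd.DataFrame, genes: pd.DataFrame, flank_bp: int = 0
) -> dict[str, np.ndarray]:
    """Map gene_id -> sorted indices of SNPs within the (flanked) gene body.

    Boundaries are inclusive on both sides; a SNP inside two overlapping
    genes is assigned to both.
    """
    out: dict[str, np.ndarray] = {}
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    chrom_arr = variants["chrom"].to_numpy()
    pos_arr = variants["pos_bp"].to_numpy()
    for chrom in pd.unique(variants["chrom"]):
        mask = np.flatnonzero(chrom_arr == chrom)
        by_chrom[str(chrom)] = (pos_arr[mask], mask)
    for row in genes.itertuples():
        chrom = str(row.chrom)
        if chrom not in by_chrom:
            out[row.gene_id] = np.empty(0, dtype=np.intp)
            continue
        pos, idx = by_chrom[chrom]
        lo = np.searchsorted(pos, row.start_bp - flank_bp, side="left")
        hi = np.searchsorted(pos, row.end_bp + flank_bp, side="right")
        out[row.gene_id] = idx[lo:hi]
    return out


def summarize_gene(
    abs_ihs: np.ndarray, lrt: np.ndarray, statistic: str
) -> tuple[float, float, int, int]:
    """Gene summary (s_ihs, s_lrt, n_ihs, n_lrt) over defined SNP scores.

    ``abs_ihs`` are |standardized iHS| values (undefined entries NaN);
    undefined scores are omitted from the summary and counted separately.
    """
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    fn = np.mean if statistic == "mean" else np.median
    a = np.asarray(abs_ihs, dtype=float)
    l = np.asarray(lrt, dtype=float)
    a = a[np.isfinite(a)]
    l = l[np.isfinite(l)]
    s_ihs = float(fn(a)) if a.size else float("nan")
    s_lrt = float(fn(l)) if l.size else float("nan")
    return s_ihs, s_lrt, a.size, l.size


def empirical_pvalue(value: float, background: np.ndarray) -> float:
    """Right-tail empirical P = (1 + #{background >= value}) / (1 + N)."""
    bg = np.asarray(background, dtype=float)
    bg = bg[np.isfinite(bg)]
    if bg.size == 0:
        raise ValueError("empirical_pvalue needs a non-empty background")
    return float((1 + np.count_nonzero(bg >= value)) / (1 + bg.size))


def _empirical_pvalues_vec(
    values: np.ndarray, background: np.ndarray, is_member: np.ndarray | None = None
) -> np.ndarray:
    """Vectorized right-tail empirical P-values against a background.

    Rows flagged in ``is_member`` belong to the background themselves and
    are ranked leave-self-out (their own tie with themselves is removed),
    so under the null their P-values are exactly uniform on {1/N, ..., 1}.
    """
    finite = np.isfinite(background)
    bg = np.sort(background[finite])
    if bg.size == 0:
        raise ValueError("empirical P-values need a non-empty background")
    v = np.asarray(values, dtype=float)
    out = np.full(v.shape, np.nan)
    ok = np.isfinite(v)
    # count of background >= value via sorted search
    ge = (bg.size - np.searchsorted(bg, v[ok], side="left")).astype(float)
    r = 1.0 + ge
    n = 1.0 + bg.size
    if is_member is not None:
        member = np.asarray(is_member, dtype=bool)[ok]
        r[member] -= 1.0  # drop the self-comparison (always a >= tie)
        out[ok] = np.where(member, r / (n - 1.0), r / n)
    else:
        out[ok] = r / n
    return out


def fisher_combine(p_ihs: float, p_lrt: float) -> tuple[float, float]:
    """Fisher's combination of two P-values.

    Returns (z_f, p_zf) with z_f = -2 (ln p_ihs + ln p_lrt) and p_zf the
    chi-square(4) survival function at z_f.  Inputs must lie in (0, 1];
    empirical P-values built with the (r+1)/(n+1) convention never reach 0.
    """
    for p in (p_ihs, p_lrt):
        if not (0.0 < p <= 1.0):
            raise ValueError(f"P-values must lie in (0, 1], got {p}")
    z = -2.0 * (np.log(p_ihs) + np.log(p_lrt))
    return float(z), float(chi2.sf(z, df=4))


def run_gene_scan(
    snp_scores: pd.DataFrame,
    genes: pd.DataFrame,
    comparisons: list[str],
    statistics: tuple[str, ...] = ("mean", "median"),
    min_snps: int = 1,
    flank_bp: int = 0,
    background_gene_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Gene-level table: one row per gene x comparison x summary statistic.

    ``snp_scores`` must carry ``ihs_std`` and one ``lrt_<label>`` column per
    comparison label.  The empirical background is the gene-level score
    distribution over ``background_gene_ids`` (default: every annotated
    gene) within the same comparison and statistic; genes whose defined-SNP
    count falls below ``min_snps`` carry NaN rows rather than being dropped
    silently.
    """
    if not comparisons:
        raise ValueError("at least one comparison is required")
    assignment = assign_snps_to_genes(snp_scores, genes, flank_bp=flank_bp)
    abs_ihs = np.abs(snp_scores["ihs_std"].to_numpy(dtype=float))
    gene_ids = genes["gene_id"].tolist()
    bg_set = set(background_gene_ids) if background_gene_ids is not None else set(gene_ids)

    rows = []
    for comp in comparisons:
        lrt_col = f"lrt_{comp}"
        if lrt_col not in snp_scores.columns:
            raise KeyError(f"snp_scores lacks column {lrt_col!r}")
        lrt = snp_scores[lrt_col].to_numpy(dtype=float)
        for stat in statistics:
            recs = []
            for gid in gene_ids:
                idx = assignment[gid]
                s_ihs, s_lrt, n_ihs, n_lrt = summarize_gene(
                    abs_ihs[idx], lrt[idx], stat
                )
                if n_ihs < min_snps:
                    s_ihs = float("nan")
                if n_lrt < min_snps:
                    s_lrt = float("nan")
                recs.append((gid, idx.size, n_ihs, n_lrt, s_ihs, s_lrt))
            block = pd.DataFrame(
                recs, columns=["gene_id", "n_snps", "n_ihs", "n_lrt", "s_ihs", "s_lrt"]
            )
            in_bg = block["gene_id"].isin(bg_set).to_numpy()
            p_ihs = _empirical_pvalues_vec(
                block["s_ihs"].to_numpy(),
                block.loc[in_bg, "s_ihs"].to_numpy(),
                is_member=in_bg & block["s_ihs"].notna().to_numpy(),
            )
            p_lrt = _empirical_pvalues_vec(
                block["s_lrt"].to_numpy(),
                block.loc[in_bg, "s_lrt"].to_numpy(),
                is_member=in_bg & block["s_lrt"].notna().to_numpy(),
            )
            with np.errstate(invalid="ignore"):
                z_f = -2.0 * (np.log(p_ihs) + np.log(p_lrt))
            p_zf = np.where(np.isfinite(z_f), chi2.sf(z_f, df=4), np.nan)
            block["p_ihs"] = p_ihs
            block["p_lrt"] = p_lrt
            block["z_f"] = z_f
            block["p_zf"] = p_zf
            block.insert(1, "comparison", comp)
            block.insert(2, "statistic", stat)
            rows.append(block)
    return pd.concat(rows, ignore_index=True)[GENE_SCORE_COLUMNS]
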