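"""Matched-control gene-set enrichment for an excess of selection signals.

Candidate genes could differ from the genomic background in exactly the
covariates that drive scan power — local recombination rate and the number
of SNPs analyzed — so the null distribution is built from control sets
matched on those covariates: for each candidate, a pool of the k most
similar background genes (Euclidean distance on z-scored covariates), then
control sets assembled by drawing one gene per pool.  The enrichment
P-value is the (r+1)/(n+1)-corrected fraction of control sets whose signal
count reaches the candidates' count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hapio import GeneticMap

AT_LEAST_RULES = (1, 2, 3)


@dataclass
class EnrichmentResult:
    rule: str  # comparison label or "at_least_k"
    statistic: str
    candidate_count: int
    null_counts: np.ndarray
    p_enrich: float


def gene_covariates(
    genes: pd.DataFrame,
    gmap: GeneticMap,
    assignment: dict[str, np.ndarray],
    min_span_bp: int = 1_000,
    rate_window_bp: int = 10_000,
) -> pd.DataFrame:
    """Per-gene matching covariates: recombination rate (cM/Mb) across the
    gene interval and the number of SNPs assigned.

    Genes spanning less than ``min_span_bp`` use a ``rate_window_bp``
    window centered on the gene midpoint for the rate.
    """
    rows = []
    for row in genes.itertuples():
        chrom = str(row.chrom)
        start, end = int(row.start_bp), int(row.end_bp)
        span = end - start + 1
        if span < min_span_bp:
            mid = (start + end) // 2
            start = mid - rate_window_bp // 2
            end = mid + rate_window_bp // 2
            span = end - start + 1
        cm = gmap.interpolate(chrom, np.array([start, end], dtype=float))
        rate = float(cm[1] - cm[0]) / (span / 1e6)
        rows.append((row.gene_id, max(rate, 0.0), int(assignment[row.gene_id].size)))
    return pd.DataFrame(rows, columns=["gene_id", "recomb_rate", "n_snps"])


def _zscore_columns(mat: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """z-score columns of ``mat`` by the mean/SD of ``ref``; zero-variance
    columns contribute nothing to distances."""
    mean = ref.mean(axis=0)
    sd = ref.std(axis=0, ddof=0)
    safe = np.where(sd > 0, sd, 1.0)
    z = (mat - mean) / safe
    z[:, sd == 0] = 0.0
    return z


def match_control_pool(
    candidate_id: str,
    covariates: pd.DataFrame,
    background_ids: list[str],
    k: int = 1000,
    zscore: bool = True,
) -> list[str]:
    """The k background genes most similar to the candidate.

    Distance is Euclidean on (recomb_rate, n_snps), z-scored over the
    background by default; ties break lexicographically on gene_id and the
    candidate never enters its own pool.
    """
    cov = covariates.set_index("gene_id")
    bg = [g for g in background_ids if g != candidate_id]
    if len(bg) <= k:
        raise ValueError(
            f"background ({len(bg)}) must exceed pool size k={k}"
        )
    bg_mat = cov.loc[bg, ["recomb_rate", "n_snps"]].to_numpy(dtype=float)
    cand = cov.loc[[candidate_id], ["recomb_rate", "n_snps"]].to_numpy(dtype=float)
    if zscore:
        cand = _zscore_columns(cand, bg_mat)
        bg_mat = _zscore_columns(bg_mat, bg_mat)
    d = np.sqrt(((bg_mat - cand[0]) ** 2).sum(axis=1))
    order = np.lexsort((np.asarray(bg, dtype=object), d))
    return [bg[i] for i in order[:k]]


def build_control_sets(
    pools: dict[str, list[str]],
    n_sets: int = 1000,
    seed: int | None = None,
    max_redraws: int = 100,
) -> list[list[str]]:
    """Assemble ``n_sets`` control sets, one gene drawn uniformly per
    candidate's pool; within-set duplicates are resolved by redrawing."""
    rng = np.random.default_rng(seed)
    cand_ids = list(pools)
    pool_arrays = [np.asarray(pools[c], dtype=object) for c in cand_ids]
    sets: list[list[str]] = []
    for _ in range(n_sets):
        chosen: list[str] = []
        taken: set[str] = set()
        for arr in pool_arrays:
            pick = arr[rng.integers(arr.size)]
            tries = 0
            while pick in taken:
                tries += 1
                if tries > max_redraws:
                    raise RuntimeError(
                        "could not resolve duplicate control genes after "
                        f"{max_redraws} redraws (pathological pool overlap)"
                    )
                pick = arr[rng.integers(arr.size)]
            taken.add(pick)
            chosen.append(str(pick))
        sets.append(chosen)
    return sets


def count_signals(
    gene_table: pd.DataFrame,
    gene_set: list[str],
    alpha: float = 0.05,
    rule: str | int = 1,
    statistic: str = "mean",
) -> int:
    """Number of genes in ``gene_set`` with a selection signal.

    String rule = one comparison label: count genes with p_zf < alpha in
    that comparison.  Integer rule k: count genes significant in at least k
    comparisons (same summary statistic).  The threshold is strict.
    """
    sub = gene_table[
        (gene_table["statistic"] == statistic)
        & gene_table["gene_id"].isin(set(gene_set))
    ]
    sig = sub[sub["p_zf"] < alpha]
    if isinstance(rule, str):
        return int((sig["comparison"] == rule).sum())
    per_gene = sig.groupby("gene_id").size()
    return int((per_gene >= int(rule)).sum())


def enrichment_test(
    candidate_count: int, null_counts: np.ndarray, strict: bool = False
) -> float:
    """Empirical enrichment P = (1 + #{null >= count}) / (1 + n_sets).

    ``strict=True`` switches the comparison to a strict ``>`` (the
    uncorrected "greater than observed" reading).
    """
    null_counts = np.asarray(null_counts)
    if null_counts.size == 0:
        raise ValueError("null_counts must be non-empty")
    if strict:
        r = int((null_counts > candidate_count).sum())
    else:
        r = int((null_counts >= candidate_count).sum())
    return float((1 + r) / (1 + null_counts.size))


def run_enrichment(
    gene_table: pd.DataFrame,
    candidates: list[str],
    covariates: pd.DataFrame,
    comparisons: list[str],
    statistics: tuple[str, ...] = ("mean", "median"),
    alpha: float = 0.05,
    k_pool: int = 1000,
    n_sets: int = 1000,
    seed: int | None = None,
    strict: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full enrichment analysis over per-comparison and at-least-k rules.

    Returns (summary, null_long): a summary row per rule x statistic with
    the candidate count, null quantiles and p_enrich, and a long-format
    table of all null counts (violin-plot ready).
    """
    scored = set(gene_table["gene_id"])
    background = sorted(g for g in scored if g not in set(candidates))
    pools = {
        c: match_control_pool(c, covariates, background, k=k_pool)
        for c in candidates
    }
    sets = build_control_sets(pools, n_sets=n_sets, seed=seed)

    rules: list[str | int] = list(comparisons) + [
        k for k in AT_LEAST_RULES if k <= len(comparisons)
    ]
    summary_rows = []
    null_rows = []
    for stat in statistics:
        # one significance indicator per gene and rule, so set counting is a
        # vectorized lookup rather than a table scan per control set
        sub = gene_table[gene_table["statistic"] == stat]
        # .pivot keeps genes whose p_zf is NaN (no defined score = no signal)
        pivot = sub.pivot(index="gene_id", columns="comparison", values="p_zf") < alpha
        gene_index = {g: i for i, g in enumerate(pivot.index)}
        sig = {}
        for comp in comparisons:
            sig[comp] = pivot[comp].to_numpy()
        n_sig = pivot[list(comparisons)].to_numpy().sum(axis=1)
        for k in AT_LEAST_RULES:
            if k <= len(comparisons):
                sig[k] = n_sig >= k
        cand_idx = np.array([gene_index[g] for g in candidates])
        set_idx = [np.array([gene_index[g] for g in s]) for s in sets]
        for rule in rules:
            vec = sig[rule]
            cand_count = int(vec[cand_idx].sum())
            nulls = np.array([int(vec[s].sum()) for s in set_idx])
            p = enrichment_test(cand_count, nulls, strict=strict)
            rule_name = rule if isinstance(rule, str) else f"at_least_{rule}"
            summary_rows.append(
                {
                    "rule": rule_name,
                    "statistic": stat,
                    "candidate_count": cand_count,
                    "null_mean": float(nulls.mean()),
                    "null_q05": float(np.quantile(nulls, 0.05)),
                    "null_q50": float(np.quantile(nulls, 0.50)),
                    "null_q95": float(np.quantile(nulls, 0.95)),
                    "p_enrich": p,
                }
            )
            null_rows.append(
                pd.DataFrame(
                    {
                        "rule": rule_name,
                        "statistic": stat,
                        "set_index": np.arange(n_sets),
                        "count": nulls,
                    }
                )
            )
    return pd.DataFrame(summary_rows), pd.concat(null_rows, ignore_index=True)
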