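"""End-to-end orchestration: simulate/load -> QC -> per-SNP statistics ->
gene scores -> enrichment, with reproducible run manifests.

Every stage consumes and produces plain data structures (and TSV files when
run through :func:`run_pipeline`), so any stage can be rerun standalone.
Two runs with the same configuration and seed produce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, enrich, genescore, hapio, selstats, synthdata

logger = logging.getLogger("sweepscan")


class StageError(RuntimeError):
    """An error raised by a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


@dataclass
class Comparison:
    """One reference configuration: the target population is contrasted
    against a South-American reference and a global (outgroup) reference."""

    label: str
    ref_sa: str
    ref_global: str


@dataclass
class ScanParams:
    alpha: float = 0.05
    snp_missing_max: float = 0.02
    ind_missing_max: float = 0.05
    maf_min: float = 0.01
    ehh_cutoff: float = 0.05
    max_gap_bp: int = 200_000
    freq_min: float = 0.05
    freq_max: float = 0.95
    bin_width: float = 0.025
    keep_truncated: bool = False
    flank_bp: int = 0
    min_snps: int = 1
    k_pool: int = 1000
    n_sets: int = 1000
    statistics: tuple[str, ...] = ("mean", "median")
    exclude_candidates_from_background: bool = False


@dataclass
class PipelineConfig:
    seed: int
    simulate: synthdata.SimConfig | None = None
    vcf_paths: dict[str, str] = field(default_factory=dict)
    map_path: str | None = None
    genes_path: str | None = None
    target: str = "target"
    comparisons: list[Comparison] = field(
        default_factory=lambda: [Comparison("sa_ref", "ref_sa", "ref_global")]
    )
    params: ScanParams = field(default_factory=ScanParams)
    candidates: list[str] = field(default_factory=list)  # empty: use sweep truth

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulate", None)
        if sim is not None:
            sim.setdefault("seed", raw.get("seed"))
            if "populations" in sim:
                sim["populations"] = [
                    synthdata.PopulationSpec(**p) for p in sim["populations"]
                ]
            if "sweeps" in sim:
                sim["sweeps"] = [synthdata.SweepSpec(**s) for s in sim["sweeps"]]
            sim = synthdata.SimConfig(**sim)
        comps = [Comparison(**c) for c in raw.pop("comparisons", [])]
        params = ScanParams(**raw.pop("params", {}))
        cfg = cls(simulate=sim, params=params, **raw)
        if comps:
            cfg.comparisons = comps
        return cfg


@dataclass
class ScanResult:
    snp_table: pd.DataFrame
    gene_table: pd.DataFrame
    trees: dict[str, selstats.DriftTree]
    qc_reports: list[hapio.QCReport]
    covariates: pd.DataFrame | None = None
    enrichment: pd.DataFrame | None = None
    null_counts: pd.DataFrame | None = None
    candidate_report: pd.DataFrame | None = None


def run_scan(
    haps: dict[str, hapio.HaplotypeMatrix],
    genes: pd.DataFrame,
    gmap: hapio.GeneticMap,
    target: str,
    comparisons: list[Comparison],
    params: ScanParams,
    candidates: list[str] | None = None,
    seed: int | None = None,
) -> ScanResult:
    """The full in-memory analysis used by the CLI and the test harness."""
    if not comparisons:
        raise StageError("snpstats", "at least one comparison must be configured")

    t0 = time.perf_counter()
    qc_haps = {}
    qc_reports = []
    for label, hap in haps.items():
        try:
            filtered, report = hapio.qc_filter(
                hap,
                snp_missing_max=params.snp_missing_max,
                ind_missing_max=params.ind_missing_max,
                maf_min=params.maf_min,
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError("qc", f"{label}: {exc}") from exc
        qc_haps[label] = filtered
        qc_reports.append(report)
        logger.info(
            "qc %s: %d -> %d SNPs, %d -> %d individuals",
            label, report.n_snps_in, report.n_snps_out,
            report.n_individuals_in, report.n_individuals_out,
        )
    qc_haps = hapio.intersect_variants(qc_haps)
    n_common = qc_haps[target].n_variants
    logger.info("variants common to all populations: %d", n_common)
    if n_common == 0:
        raise StageError("qc", "no variants survive QC in all populations")

    try:
        snp_table = selstats.ihs_scan(
            qc_haps[target],
            gmap,
            ehh_cutoff=params.ehh_cutoff,
            max_gap_bp=params.max_gap_bp,
            freq_range=(params.freq_min, params.freq_max),
            bin_width=params.bin_width,
            keep_truncated=params.keep_truncated,
        )
        trees = {}
        for comp in comparisons:
            lrt, tree = selstats.lrt_scan(
                qc_haps, target, comp.ref_sa, comp.ref_global
            )
            snp_table[f"lrt_{comp.label}"] = lrt
            trees[comp.label] = tree
            logger.info(
                "comparison %s: drift c=%s (Fst %s)",
                comp.label, np.round(tree.c, 4).tolist(), tree.fst_pairs,
            )
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("snpstats", str(exc)) from exc
    logger.info(
        "snpstats: %d SNPs, %d with defined iHS (%.1f s)",
        len(snp_table),
        int(np.isfinite(snp_table["ihs_std"]).sum()),
        time.perf_counter() - t0,
    )

    try:
        background = None
        if params.exclude_candidates_from_background and candidates:
            background = [g for g in genes["gene_id"] if g not in set(candidates)]
        gene_table = genescore.run_gene_scan(
            snp_table,
            genes,
            [c.label for c in comparisons],
            statistics=params.statistics,
            min_snps=params.min_snps,
            flank_bp=params.flank_bp,
            background_gene_ids=background,
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("genescan", str(exc)) from exc
    logger.info("genescan: %d gene rows", len(gene_table))

    covariates = enrichment = null_counts = None
    if candidates:
        try:
            assignment = genescore.assign_snps_to_genes(
                snp_table, genes, flank_bp=params.flank_bp
            )
            covariates = enrich.gene_covariates(genes, gmap, assignment)
            enrichment, null_counts = enrich.run_enrichment(
                gene_table,
                list(candidates),
                covariates,
                [c.label for c in comparisons],
                statistics=params.statistics,
                alpha=params.alpha,
                k_pool=params.k_pool,
                n_sets=params.n_sets,
                seed=seed,
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError("enrich", str(exc)) from exc
        logger.info("enrich: %d rule rows", len(enrichment))

    candidate_report = report_candidates(gene_table, params.alpha)
    return ScanResult(
        snp_table=snp_table,
        gene_table=gene_table,
        trees=trees,
        qc_reports=qc_reports,
        covariates=covariates,
        enrichment=enrichment,
        null_counts=null_counts,
        candidate_report=candidate_report,
    )


def report_candidates(gene_table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene count of significant comparisons, one column per summary
    statistic; genes with no signal anywhere are omitted."""
    sig = gene_table[gene_table["p_zf"] < alpha]
    counts = (
        sig.groupby(["gene_id", "statistic"]).size().unstack(fill_value=0)
    )
    counts = counts.rename(columns=lambda s: f"n_sig_{s}")
    counts = counts.reset_index()
    return counts.sort_values("gene_id").reset_index(drop=True)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """File-level pipeline: writes every stage TSV, a manifest and a log.

    Returns the run directory.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    t0 = time.perf_counter()
    try:
        candidates = list(config.candidates)
        if config.simulate is not None:
            ds = synthdata.simulate_dataset(config.simulate)
            haps, genes, gmap = ds.haps, ds.genes, ds.gmap
            target = config.simulate.target
            if not candidates and len(ds.truth):
                candidates = ds.truth["gene_id"].astype(str).tolist()
            ds.truth.to_csv(outdir / "sweep_truth.tsv", sep="\t", index=False)
        else:
            try:
                if not config.vcf_paths or config.map_path is None or config.genes_path is None:
                    raise StageError(
                        "hapio", "vcf_paths, map_path and genes_path are all required"
                    )
                haps = {}
                for label, path in config.vcf_paths.items():
                    hap, _ = hapio.read_phased_vcf(path, population_label=label)
                    haps[label] = hap
                gmap = hapio.read_genetic_map(config.map_path)
                genes = hapio.read_gene_bed(config.genes_path)
                target = config.target
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001
                raise StageError("hapio", str(exc)) from exc

        result = run_scan(
            haps,
            genes,
            gmap,
            target,
            config.comparisons,
            config.params,
            candidates=candidates,
            seed=config.seed,
        )

        qc = pd.concat([r.to_frame() for r in result.qc_reports], ignore_index=True)
        qc.to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
        result.snp_table.to_csv(outdir / "snp_scores.tsv", sep="\t", index=False)
        result.gene_table.to_csv(outdir / "gene_scores.tsv", sep="\t", index=False)
        if result.candidate_report is not None:
            result.candidate_report.to_csv(
                outdir / "candidate_report.tsv", sep="\t", index=False
            )
        if result.enrichment is not None:
            result.enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            result.null_counts.to_csv(outdir / "null_counts.tsv", sep="\t", index=False)
        if result.covariates is not None:
            result.covariates.to_csv(outdir / "gene_covariates.tsv", sep="\t", index=False)

        manifest = {
            "package_version": __version__,
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "n_snps_scored": int(len(result.snp_table)),
            "n_gene_rows": int(len(result.gene_table)),
            "comparisons": [c.label for c in config.comparisons],
            "elapsed_s": round(time.perf_counter() - t0, 2),
            "versions": {
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        logger.info("pipeline complete in %.1f s", time.perf_counter() - t0)
        return outdir
    finally:
        logger.removeHandler(handler)
        handler.close()
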