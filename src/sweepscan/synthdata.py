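"""Seeded multi-population haplotype simulator with injected hard sweeps.

The generator emulates the structure of SNP-array data from one target and
two reference populations:

* **Allele frequencies** follow the Balding-Nichols model: an ancestral
  frequency mu per SNP, then an independent Beta draw per population branch
  with drift parameter c_i, so E[x_i] = mu and Var[x_i] = c_i mu(1-mu).
  Default drift (0.02, 0.06, 0.10) yields pairwise genome-wide Fst of
  roughly 0.08 / 0.12 / 0.16.
* **Haplotypes and LD** come from founder-mosaic (Li-Stephens-style)
  copying: a pool of founder haplotypes drawn site-wise Bernoulli(x_i),
  each sample haplotype a mosaic over founders switching at ``switch_rate``
  per cM, so linkage disequilibrium decays with genetic distance.
* **Hard sweeps** are injected by copying one derived-carrier haplotype
  over other haplotypes around a focal SNP until the derived allele reaches
  a target frequency, with per-replacement window half-lengths drawn
  exponentially in cM so haplotype homozygosity decays away from the focal
  SNP.  Ground truth (gene, focal SNP, realized frequency) is recorded.

Everything is deterministic given (config, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import hapio
from .hapio import GeneticMap, HaplotypeMatrix


@dataclass
class PopulationSpec:
    label: str
    n_individuals: int = 30
    drift: float = 0.02  # Balding-Nichols branch parameter c, in (0, 1)


@dataclass
class SweepSpec:
    gene_id: str | None  # None: assign automatically at simulation time
    final_freq: float = 0.9


@dataclass
class SimConfig:
    """Study-condition defaults: 3 populations x 30 individuals, 2
    chromosomes x 5,000 SNPs over 50 Mb each, 200 genes of 50 kb."""

    seed: int
    populations: list[PopulationSpec] = field(
        default_factory=lambda: [
            PopulationSpec("target", 30, 0.02),
            PopulationSpec("ref_sa", 30, 0.06),
            PopulationSpec("ref_global", 30, 0.10),
        ]
    )
    n_chroms: int = 2
    n_snps_per_chrom: int = 5000
    chrom_length_bp: int = 50_000_000
    map_anchor_spacing_bp: int = 1_000_000
    recomb_rate_log_mean: float = 0.0  # ln(cM/Mb); exp(0) = 1 cM/Mb
    recomb_rate_log_sd: float = 0.5
    founder_count: int = 20
    switch_rate: float = 2.0  # mosaic switches per cM
    mu_low: float = 0.05  # ancestral-frequency sampler: Uniform(mu_low, mu_high)
    mu_high: float = 0.95
    n_genes: int = 200
    gene_span_bp: int = 50_000
    sweeps: list[SweepSpec] = field(default_factory=list)
    sweep_scale_cm: float | None = None  # None: 0.5 / ln(1/(1-final_freq))

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("SimConfig.seed is mandatory")
        for p in self.populations:
            if not 0.0 < p.drift < 1.0:
                raise ValueError(f"drift for {p.label} must lie in (0, 1)")
        for s in self.sweeps:
            if not 0.0 < s.final_freq <= 1.0:
                raise ValueError("sweep final_freq must lie in (0, 1]")

    @property
    def target(self) -> str:
        return self.populations[0].label


@dataclass
class SweepTruth:
    gene_id: str
    chrom: str
    focal_pos: int
    final_freq: float
    seed: int


@dataclass
class SimulatedDataset:
    config: SimConfig
    haps: dict[str, HaplotypeMatrix]
    genes: pd.DataFrame
    gmap: GeneticMap
    truth: pd.DataFrame  # columns gene_id, chrom, focal_pos, final_freq, seed

    @property
    def target_hap(self) -> HaplotypeMatrix:
        return self.haps[self.config.target]


def neutral_config(seed: int, **overrides) -> SimConfig:
    return SimConfig(seed=seed, **overrides)


def sweep_config(
    seed: int, n_sweeps: int = 5, final_freq: float = 0.9, **overrides
) -> SimConfig:
    sweeps = [SweepSpec(None, final_freq) for _ in range(n_sweeps)]
    return SimConfig(seed=seed, sweeps=sweeps, **overrides)


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def simulate_frequencies(
    config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """(mu, x) with x of shape (n_pops, n_snps): Balding-Nichols draws."""
    m = config.n_chroms * config.n_snps_per_chrom
    mu = rng.uniform(config.mu_low, config.mu_high, size=m)
    x = np.empty((len(config.populations), m))
    for i, pop in enumerate(config.populations):
        c = pop.drift
        a = mu * (1 - c) / c
        b = (1 - mu) * (1 - c) / c
        x[i] = rng.beta(a, b)
    return mu, x


def _simulate_map(config: SimConfig, rng: np.random.Generator) -> GeneticMap:
    anchors = {}
    for ci in range(config.n_chroms):
        bp = np.arange(1, config.chrom_length_bp + 2, config.map_anchor_spacing_bp)
        rates = rng.lognormal(
            config.recomb_rate_log_mean, config.recomb_rate_log_sd, size=bp.size - 1
        )
        cm = np.concatenate(
            ([0.0], np.cumsum(rates * np.diff(bp) / 1e6))
        )
        anchors[f"chr{ci + 1}"] = (bp, cm)
    return GeneticMap(anchors)


def _simulate_positions(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    frames = []
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        # rejection sampling: unique uniform positions without materializing
        # the full coordinate range
        n = config.n_snps_per_chrom
        draws = np.unique(rng.integers(1, config.chrom_length_bp + 1, size=2 * n))
        while draws.size < n:
            extra = rng.integers(1, config.chrom_length_bp + 1, size=n)
            draws = np.unique(np.concatenate([draws, extra]))
        pos = np.sort(rng.choice(draws, size=n, replace=False))
        frames.append(pd.DataFrame({"chrom": chrom, "pos_bp": pos}))
    v = pd.concat(frames, ignore_index=True)
    v["variant_id"] = "snp_" + v["chrom"].astype(str) + "_" + v["pos_bp"].astype(str)
    v["ancestral_allele"] = "A"
    v["derived_allele"] = "G"
    v["polarizable"] = True
    return v


def _simulate_genes(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Non-overlapping genes: one random offset within each of n evenly
    spaced slots per chromosome."""
    per_chrom = np.full(config.n_chroms, config.n_genes // config.n_chroms)
    per_chrom[: config.n_genes % config.n_chroms] += 1
    rows = []
    gi = 0
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        n = int(per_chrom[ci])
        slot = config.chrom_length_bp // n
        if slot <= config.gene_span_bp:
            raise ValueError("gene span too large for non-overlapping placement")
        for s in range(n):
            gi += 1
            offset = int(rng.integers(0, slot - config.gene_span_bp))
            start = s * slot + offset + 1
            rows.append(
                (f"G{gi:04d}", chrom, start, start + config.gene_span_bp - 1, False)
            )
    return pd.DataFrame(rows, columns=hapio.GENE_COLUMNS)


def simulate_haplotypes(
    freqs: np.ndarray,
    variants: pd.DataFrame,
    gmap: GeneticMap,
    config: SimConfig,
    rng: np.random.Generator,
) -> dict[str, HaplotypeMatrix]:
    """Founder-mosaic haplotypes for every population.

    With switch_rate = 0 every sample haplotype is an exact founder copy;
    otherwise mosaics switch founders between adjacent SNPs with
    probability 1 - exp(-switch_rate * d_cM), restarting on each
    chromosome.
    """
    chrom_arr = variants["chrom"].to_numpy()
    pos_arr = variants["pos_bp"].to_numpy()
    pos_cm = np.empty(len(variants))
    for chrom in pd.unique(variants["chrom"]):
        mask = chrom_arr == chrom
        pos_cm[mask] = gmap.interpolate(str(chrom), pos_arr[mask])
    d_cm = np.diff(pos_cm)
    new_chrom = chrom_arr[1:] != chrom_arr[:-1]
    p_switch = 1.0 - np.exp(-config.switch_rate * np.maximum(d_cm, 0.0))
    p_switch[new_chrom] = 1.0  # independent restart per chromosome

    out = {}
    m = len(variants)
    F = config.founder_count
    for i, pop in enumerate(config.populations):
        founders = (rng.random((F, m)) < freqs[i]).astype(np.int8)
        nh = 2 * pop.n_individuals
        switches = rng.random((nh, m - 1)) < p_switch
        seg_id = np.zeros((nh, m), dtype=np.int32)
        seg_id[:, 1:] = np.cumsum(switches, axis=1)
        n_segs = seg_id[:, -1].max() + 1
        choices = rng.integers(0, F, size=(nh, n_segs))
        founder_idx = np.take_along_axis(choices, seg_id, axis=1)
        h = founders[founder_idx, np.arange(m)[None, :]]
        sample_ids = [f"{pop.label}_{k:03d}" for k in range(pop.n_individuals)]
        hap = HaplotypeMatrix(pop.label, h, sample_ids, variants.copy())
        hap.refresh_variant_stats()
        out[pop.label] = hap
    return out


def inject_sweep(
    hap: HaplotypeMatrix,
    gene: pd.Series,
    final_freq: float,
    gmap: GeneticMap,
    rng: np.random.Generator,
    scale_cm: float | None = None,
    low_freq_max: float = 0.25,
    ref_freqs: np.ndarray | None = None,
    seed: int = 0,
) -> SweepTruth:
    """Inject a stylized hard sweep at a gene (in place).

    The focal SNP is the gene SNP nearest the midpoint among those whose
    derived allele is still rare (frequency <= ``low_freq_max``) — a hard
    sweep rises from low frequency, and injecting on an already-common
    allele would produce no haplotype signal.  When reference-population
    frequencies are supplied (``ref_freqs``, one row per population), the
    allele must also be rare in every reference so the injected sweep is
    genuinely target-specific — otherwise there is no differentiation
    signal to recover.  If no gene SNP qualifies, the constraint relaxes
    to the target population alone, then to the rarest carrier SNP.
    One derived carrier is the
    sweeping lineage, and non-carrier haplotypes are overwritten with its
    alleles over windows of exponential cM half-length until the derived
    frequency reaches ``final_freq``.
    """
    v = hap.variants
    chrom = str(gene.chrom)
    in_gene = np.flatnonzero(
        (v["chrom"].to_numpy() == chrom)
        & (v["pos_bp"].to_numpy() >= gene.start_bp)
        & (v["pos_bp"].to_numpy() <= gene.end_bp)
    )
    if in_gene.size == 0:
        raise ValueError(f"gene {gene.gene_id} contains no SNPs")
    mid = (gene.start_bp + gene.end_bp) / 2
    h = hap.haplotypes
    freq = hap.derived_freq()[in_gene]
    carriers_present = freq > 0
    if not carriers_present.any():
        raise ValueError(f"no derived carrier at any SNP of gene {gene.gene_id}")
    rare = carriers_present & (freq <= low_freq_max)
    if ref_freqs is not None:
        rare_everywhere = rare & np.all(
            ref_freqs[:, in_gene] <= low_freq_max, axis=0
        )
        if rare_everywhere.any():
            rare = rare_everywhere
    if rare.any():
        pool = in_gene[rare]
        focal = int(pool[np.argmin(np.abs(v["pos_bp"].to_numpy()[pool] - mid))])
    else:
        pool = in_gene[carriers_present]
        focal = int(pool[np.argmin(freq[carriers_present])])

    chrom_mask = v["chrom"].to_numpy() == chrom
    cm_all = np.full(len(v), np.nan)
    cm_all[chrom_mask] = gmap.interpolate(chrom, v["pos_bp"].to_numpy()[chrom_mask])
    focal_cm = cm_all[focal]

    carriers = np.flatnonzero(h[:, focal] == 1)
    sweep_hap = int(rng.choice(carriers))
    n_target = int(round(final_freq * hap.n_haplotypes))
    need = n_target - carriers.size
    if scale_cm is None:
        scale_cm = 0.5 / np.log(1.0 / (1.0 - min(final_freq, 1 - 1e-9)))
    if need > 0:
        non_carriers = np.flatnonzero(h[:, focal] != 1)
        recipients = rng.permutation(non_carriers)[:need]
        for r in recipients:
            half = rng.exponential(scale_cm)
            window = chrom_mask & (np.abs(cm_all - focal_cm) <= half)
            h[r, window] = h[sweep_hap, window]
    hap.refresh_variant_stats()
    realized = float((h[:, focal] == 1).mean())
    return SweepTruth(
        gene_id=str(gene.gene_id),
        chrom=chrom,
        focal_pos=int(v["pos_bp"].iloc[focal]),
        final_freq=realized,
        seed=seed,
    )


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Full dataset: map, positions, genes, frequencies, haplotypes, sweeps."""
    rng = np.random.default_rng(config.seed)
    gmap = _simulate_map(config, rng)
    variants = _simulate_positions(config, rng)
    genes = _simulate_genes(config, rng)
    mu, x = simulate_frequencies(config, rng)
    haps = simulate_haplotypes(x, variants, gmap, config, rng)

    truths = []
    if config.sweeps:
        target_hap = haps[config.target]
        ref_freqs = np.vstack(
            [
                haps[p.label].derived_freq()
                for p in config.populations
                if p.label != config.target
            ]
        )
        swept_ids = _choose_sweep_genes(config, genes, target_hap, rng, ref_freqs)
        for spec, gid in zip(config.sweeps, swept_ids):
            gene = genes[genes["gene_id"] == gid].iloc[0]
            truths.append(
                inject_sweep(
                    target_hap,
                    gene,
                    spec.final_freq,
                    gmap,
                    rng,
                    scale_cm=config.sweep_scale_cm,
                    ref_freqs=ref_freqs,
                    seed=config.seed,
                )
            )
        genes.loc[genes["gene_id"].isin(swept_ids), "is_candidate"] = True
    truth = pd.DataFrame(
        [dataclasses.asdict(t) for t in truths],
        columns=["gene_id", "chrom", "focal_pos", "final_freq", "seed"],
    )
    return SimulatedDataset(config=config, haps=haps, genes=genes, gmap=gmap, truth=truth)


def _choose_sweep_genes(
    config: SimConfig,
    genes: pd.DataFrame,
    target_hap: HaplotypeMatrix,
    rng: np.random.Generator,
    ref_freqs: np.ndarray | None = None,
    low_freq_max: float = 0.25,
) -> list[str]:
    """Pick genes for automatic sweeps.

    Preference is given to genes holding a SNP whose derived allele is
    rare in every population (a sweep injected there is target-specific
    and carries a differentiation signal); genes with any derived carrier
    serve as fallback.
    """
    explicit = [s.gene_id for s in config.sweeps if s.gene_id is not None]
    n_auto = sum(1 for s in config.sweeps if s.gene_id is None)
    v = target_hap.variants
    freq = target_hap.derived_freq()
    rare_target = (freq > 0) & (freq <= low_freq_max)
    rare_everywhere = rare_target.copy()
    if ref_freqs is not None:
        rare_everywhere &= np.all(ref_freqs <= low_freq_max, axis=0)
    dac = target_hap.derived_allele_count()
    preferred, fallback = [], []
    for row in genes.itertuples():
        if row.gene_id in explicit:
            continue
        sel = (
            (v["chrom"].to_numpy() == row.chrom)
            & (v["pos_bp"].to_numpy() >= row.start_bp)
            & (v["pos_bp"].to_numpy() <= row.end_bp)
        )
        if np.any(rare_everywhere & sel):
            preferred.append(row.gene_id)
        elif np.any(dac[sel] > 0):
            fallback.append(row.gene_id)
    if n_auto > len(preferred) + len(fallback):
        raise ValueError("not enough sweep-eligible genes for the requested sweeps")
    auto: list[str] = []
    if n_auto:
        take = min(n_auto, len(preferred))
        auto = list(rng.choice(np.asarray(preferred, dtype=object), take, replace=False))
        if take < n_auto:
            auto += list(
                rng.choice(
                    np.asarray(fallback, dtype=object), n_auto - take, replace=False
                )
            )
    out = []
    ai = iter(auto)
    for s in config.sweeps:
        out.append(s.gene_id if s.gene_id is not None else str(next(ai)))
    return out


# ---------------------------------------------------------------------------
# Disk round trip
# ---------------------------------------------------------------------------

def write_dataset(ds: SimulatedDataset, outdir: str | Path, force: bool = False) -> None:
    """Write one VCF per population (with INFO/AA), gene BED, map TSV,
    sweep-truth TSV and the config YAML.  Same seed -> byte-identical files."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"output directory {outdir} is not empty (use force)")
    outdir.mkdir(parents=True, exist_ok=True)
    for label, hap in ds.haps.items():
        hapio.write_phased_vcf(hap, outdir / f"{label}.vcf")
    hapio.write_gene_bed(ds.genes, outdir / "genes.bed")
    hapio.write_genetic_map(ds.gmap, outdir / "genetic_map.tsv")
    ds.truth.to_csv(outdir / "sweep_truth.tsv", sep="\t", index=False)
    (outdir / "sim_config.yaml").write_text(
        yaml.safe_dump(dataclasses.asdict(ds.config), sort_keys=True)
    )


def read_dataset(outdir: str | Path) -> SimulatedDataset:
    """Re-read a written dataset; inverse of :func:`write_dataset`."""
    outdir = Path(outdir)
    raw = yaml.safe_load((outdir / "sim_config.yaml").read_text())
    raw["populations"] = [PopulationSpec(**p) for p in raw["populations"]]
    raw["sweeps"] = [SweepSpec(**s) for s in raw["sweeps"]]
    config = SimConfig(**raw)
    haps = {}
    for pop in config.populations:
        hap, _ = hapio.read_phased_vcf(outdir / f"{pop.label}.vcf", population_label=pop.label)
        haps[pop.label] = hap
    genes = hapio.read_gene_bed(outdir / "genes.bed")
    truth = pd.read_csv(outdir / "sweep_truth.tsv", sep="\t")
    genes.loc[genes["gene_id"].isin(set(truth["gene_id"].astype(str))), "is_candidate"] = True
    gmap = hapio.read_genetic_map(outdir / "genetic_map.tsv")
    return SimulatedDataset(config=config, haps=haps, genes=genes, gmap=gmap, truth=truth)
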