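"""Phased-haplotype containers, standard-format I/O, and cohort QC filters.

Haplotypes are stored as an ``int8`` matrix of derived-allele indicators
(rows = haplotypes, two consecutive rows per diploid individual; columns =
variants; ``-1`` marks a missing allele).  Polarity is fixed at load time
from the ancestral-allele annotation, so a ``1`` always means "derived"
regardless of how REF/ALT happened to be labelled in the source VCF.

Coordinates are 1-based inclusive internally; BED input (0-based,
half-open) is converted at the boundary.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

#: columns every variant table carries
VARIANT_COLUMNS = [
    "chrom",
    "pos_bp",
    "variant_id",
    "ancestral_allele",
    "derived_allele",
    "polarizable",
    "maf",
    "missing_rate",
]


class HapIOError(ValueError):
    """Malformed input (file content or matrix invariant violation)."""


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos_bp: int
    variant_id: str
    ancestral_allele: str
    derived_allele: str
    maf: float = float("nan")
    missing_rate: float = float("nan")
    polarizable: bool = True


@dataclass
class ReaderReport:
    """Counts of records dropped while parsing a VCF."""

    n_records: int = 0
    n_kept: int = 0
    n_multiallelic_skipped: int = 0
    n_non_snp_skipped: int = 0
    n_unpolarizable: int = 0


@dataclass
class HaplotypeMatrix:
    """Phased 0/1 haplotypes for one population.

    ``haplotypes`` has shape (2 * n_individuals, n_variants); entry 1 is the
    derived allele, 0 the ancestral, -1 a missing allele.
    """

    population_label: str
    haplotypes: np.ndarray
    sample_ids: list[str]
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        h = np.asarray(self.haplotypes, dtype=np.int8)
        self.haplotypes = h
        if h.ndim != 2:
            raise HapIOError("haplotypes must be a 2-D matrix")
        if h.shape[0] % 2 != 0:
            raise HapIOError("haplotype row count must be even (diploid)")
        if h.shape[0] != 2 * len(self.sample_ids):
            raise HapIOError("sample_ids length must be half the row count")
        bad = ~np.isin(h, (0, 1, MISSING))
        if bad.any():
            raise HapIOError("haplotype entries must be 0, 1 or -1 (missing)")
        v = self.variants.reset_index(drop=True)
        for col in ("chrom", "pos_bp"):
            if col not in v.columns:
                raise HapIOError(f"variants table lacks required column {col!r}")
        if len(v) != h.shape[1]:
            raise HapIOError("variants table length must match column count")
        for _, grp in v.groupby("chrom", sort=False):
            pos = grp["pos_bp"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise HapIOError(
                    f"positions not strictly increasing on {grp['chrom'].iloc[0]}"
                )
        self.variants = v

    # -- basic shape -----------------------------------------------------
    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]

    # -- per-site summaries ----------------------------------------------
    def derived_allele_count(self) -> np.ndarray:
        return (self.haplotypes == 1).sum(axis=0)

    def called_allele_count(self) -> np.ndarray:
        return (self.haplotypes != MISSING).sum(axis=0)

    def derived_freq(self) -> np.ndarray:
        """Derived-allele frequency over non-missing alleles (NaN if none)."""
        called = self.called_allele_count()
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(called > 0, self.derived_allele_count() / called, np.nan)

    def maf(self) -> np.ndarray:
        p = self.derived_freq()
        return np.minimum(p, 1.0 - p)

    def genotype_missing(self) -> np.ndarray:
        """Boolean (n_individuals, n_variants): genotype has a missing allele."""
        miss = self.haplotypes == MISSING
        return miss[0::2] | miss[1::2]

    def snp_missing_rate(self) -> np.ndarray:
        return self.genotype_missing().mean(axis=0)

    def individual_missing_rate(self) -> np.ndarray:
        return self.genotype_missing().mean(axis=1)

    def refresh_variant_stats(self) -> None:
        self.variants = self.variants.assign(
            maf=self.maf(), missing_rate=self.snp_missing_rate()
        )

    # -- subsetting ------------------------------------------------------
    def subset_variants(self, index: np.ndarray) -> "HaplotypeMatrix":
        index = np.asarray(index)
        return HaplotypeMatrix(
            self.population_label,
            self.haplotypes[:, index],
            list(self.sample_ids),
            self.variants.iloc[index].reset_index(drop=True),
        )

    def subset_individuals(self, index: np.ndarray) -> "HaplotypeMatrix":
        index = np.asarray(index)
        rows = np.empty(2 * index.size, dtype=np.intp)
        rows[0::2] = 2 * index
        rows[1::2] = 2 * index + 1
        return HaplotypeMatrix(
            self.population_label,
            self.haplotypes[rows],
            [self.sample_ids[i] for i in index],
            self.variants.copy(),
        )

    def variant_key(self) -> pd.Index:
        return pd.Index(
            self.variants["chrom"].astype(str) + ":" + self.variants["pos_bp"].astype(str)
        )


# ---------------------------------------------------------------------------
# VCF reading / writing
# ---------------------------------------------------------------------------

def read_phased_vcf(
    path: str | Path,
    ancestral_source: str | None = "AA",
    population_label: str | None = None,
) -> tuple[HaplotypeMatrix, ReaderReport]:
    """Read a phased, biallelic-SNP VCF into a polarized haplotype matrix.

    ``ancestral_source`` names the INFO tag carrying the ancestral allele
    (default ``AA``).  Records whose tag is absent or matches neither allele
    are kept but flagged non-polarizable (they are excluded from iHS but
    remain available to frequency-based statistics).  Unphased genotypes are
    a hard error naming the record; multiallelic / non-SNP records are
    skipped and counted in the report.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if population_label is None:
        population_label = path.stem.removesuffix(".vcf")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    report = ReaderReport()
    columns: list[np.ndarray] = []
    records: list[tuple] = []
    for v in vcf:
        report.n_records += 1
        alts = [a for a in v.ALT if a not in (".", "")]
        if len(alts) != 1:
            report.n_multiallelic_skipped += 1
            continue
        ref, alt = v.REF.upper(), alts[0].upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
            report.n_non_snp_skipped += 1
            continue
        col = np.empty(2 * len(samples), dtype=np.int8)
        for i, (a0, a1, *rest) in enumerate(v.genotypes):
            phased = bool(rest[-1]) if rest else False
            if a0 < 0 and a1 < 0:
                col[2 * i] = col[2 * i + 1] = MISSING
                continue
            if not phased:
                raise HapIOError(
                    f"unphased genotype for sample {samples[i]} at {v.CHROM}:{v.POS}"
                )
            col[2 * i] = a0 if a0 >= 0 else MISSING
            col[2 * i + 1] = a1 if a1 >= 0 else MISSING

        ancestral, derived, polarizable = ref, alt, True
        if ancestral_source is not None:
            aa = v.INFO.get(ancestral_source)
            aa = str(aa).strip().upper() if aa is not None else None
            if aa == ref:
                pass
            elif aa == alt:
                # flip polarity so 1 = derived allele
                flip = col >= 0
                col[flip] = 1 - col[flip]
                ancestral, derived = alt, ref
            else:
                polarizable = False
                report.n_unpolarizable += 1
        records.append(
            (str(v.CHROM), int(v.POS), v.ID or f"{v.CHROM}:{v.POS}", ancestral, derived, polarizable)
        )
        columns.append(col)
        report.n_kept += 1

    if not records:
        raise HapIOError(f"no usable biallelic SNP records in {path}")
    variants = pd.DataFrame(
        records,
        columns=["chrom", "pos_bp", "variant_id", "ancestral_allele", "derived_allele", "polarizable"],
    )
    h = np.column_stack(columns)
    # sort by (chromosome in order of appearance, position)
    codes, _ = pd.factorize(variants["chrom"], sort=False)
    order = np.lexsort((variants["pos_bp"].to_numpy(), codes))
    variants = variants.iloc[order].reset_index(drop=True)
    h = h[:, order]
    hap = HaplotypeMatrix(population_label, h, samples, variants)
    hap.refresh_variant_stats()
    return hap, report


_GT_CODE = {0: "0", 1: "1", MISSING: "."}


def write_phased_vcf(hap: HaplotypeMatrix, path: str | Path, aa_tag: str = "AA") -> None:
    """Write a haplotype matrix as an uncompressed VCF v4.2.

    REF is written as the ancestral allele and ALT as the derived allele, and
    the ancestral allele is repeated in ``INFO/<aa_tag>`` so a round trip
    through :func:`read_phased_vcf` reproduces the matrix exactly.
    """
    v = hap.variants
    lines = io.StringIO()
    lines.write("##fileformat=VCFv4.2\n")
    lines.write(f'##INFO=<ID={aa_tag},Number=1,Type=String,Description="Ancestral allele">\n')
    lines.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    for chrom in pd.unique(v["chrom"]):
        lines.write(f"##contig=<ID={chrom}>\n")
    lines.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
    lines.write("\t".join(hap.sample_ids) + "\n")
    h = hap.haplotypes
    for j in range(hap.n_variants):
        row = v.iloc[j]
        info = f"{aa_tag}={row.ancestral_allele}" if row.polarizable else "."
        gts = "\t".join(
            f"{_GT_CODE[int(h[2 * i, j])]}|{_GT_CODE[int(h[2 * i + 1, j])]}"
            for i in range(hap.n_individuals)
        )
        lines.write(
            f"{row.chrom}\t{row.pos_bp}\t{row.variant_id}\t{row.ancestral_allele}\t"
            f"{row.derived_allele}\t.\tPASS\t{info}\tGT\t{gts}\n"
        )
    Path(path).write_text(lines.getvalue())


def polarize_by_outgroup(hap: HaplotypeMatrix, outgroup: HaplotypeMatrix) -> HaplotypeMatrix:
    """Fallback polarizer: the outgroup's major allele is taken as ancestral.

    Off by default in the pipeline; provided because ancestral states are
    sometimes unavailable as VCF annotation.  Variants absent from the
    outgroup (or with no called outgroup alleles) stay non-polarizable.
    """
    key = hap.variant_key()
    out_key = outgroup.variant_key()
    idx = pd.Index(out_key).get_indexer(key)
    out_freq = np.full(hap.n_variants, np.nan)
    present = idx >= 0
    out_freq[present] = outgroup.derived_freq()[idx[present]]

    h = hap.haplotypes.copy()
    v = hap.variants.copy()
    flip_mask = present & (out_freq > 0.5)
    keep_mask = present & (out_freq <= 0.5)
    for j in np.flatnonzero(flip_mask):
        col = h[:, j]
        valid = col >= 0
        col[valid] = 1 - col[valid]
        v.loc[j, ["ancestral_allele", "derived_allele"]] = (
            v.loc[j, "derived_allele"],
            v.loc[j, "ancestral_allele"],
        )
        v.loc[j, "polarizable"] = True
    v.loc[np.flatnonzero(keep_mask), "polarizable"] = True
    v.loc[np.flatnonzero(~present | ~np.isfinite(out_freq)), "polarizable"] = False
    new = HaplotypeMatrix(hap.population_label, h, list(hap.sample_ids), v)
    new.refresh_variant_stats()
    return new


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------

@dataclass
class GeneticMap:
    """Monotone bp -> cM lookup with piecewise-linear interpolation.

    Queries outside the anchored range are extrapolated at the flanking
    interval's cM/bp slope, so telomeric SNPs keep a defined genetic
    position.
    """

    anchors: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (bp, cm) in self.anchors.items():
            bp = np.asarray(bp, dtype=np.int64)
            cm = np.asarray(cm, dtype=float)
            order = np.argsort(bp, kind="stable")
            bp, cm = bp[order], cm[order]
            # collapse duplicate bp positions to the first occurrence
            keep = np.concatenate(([True], np.diff(bp) > 0))
            bp, cm = bp[keep], cm[keep]
            if bp.size < 2:
                raise HapIOError(f"genetic map for {chrom} needs >=2 distinct anchors")
            if np.any(np.diff(cm) < 0):
                raise HapIOError(f"genetic map for {chrom} has decreasing cM")
            clean[str(chrom)] = (bp, cm)
        self.anchors = clean

    @property
    def chromosomes(self) -> list[str]:
        return list(self.anchors)

    def interpolate(self, chrom: str, pos_bp) -> np.ndarray | float:
        """Genetic position in cM at ``pos_bp`` (scalar or array)."""
        if chrom not in self.anchors:
            raise HapIOError(f"chromosome {chrom!r} absent from genetic map")
        bp, cm = self.anchors[chrom]
        pos = np.asarray(pos_bp, dtype=float)
        out = np.interp(pos, bp, cm)
        lo_slope = (cm[1] - cm[0]) / (bp[1] - bp[0])
        hi_slope = (cm[-1] - cm[-2]) / (bp[-1] - bp[-2])
        below = pos < bp[0]
        above = pos > bp[-1]
        if np.any(below):
            out = np.where(below, cm[0] - (bp[0] - pos) * lo_slope, out)
        if np.any(above):
            out = np.where(above, cm[-1] + (pos - bp[-1]) * hi_slope, out)
        if np.isscalar(pos_bp):
            return float(out)
        return out


def interpolate_cM(gmap: GeneticMap, chrom: str, pos_bp) -> np.ndarray | float:
    """Functional alias for :meth:`GeneticMap.interpolate`."""
    return gmap.interpolate(chrom, pos_bp)


def read_genetic_map(path: str | Path) -> GeneticMap:
    """Read a HapMap-style map: header row, then ``chrom  pos_bp  cM``."""
    df = pd.read_csv(path, sep=r"\s+", header=0)
    if df.shape[1] < 3:
        raise HapIOError("genetic map needs three columns: chrom, pos_bp, cM")
    df = df.iloc[:, :3]
    df.columns = ["chrom", "pos_bp", "cM"]
    anchors = {
        str(chrom): (grp["pos_bp"].to_numpy(), grp["cM"].to_numpy())
        for chrom, grp in df.groupby("chrom", sort=False)
    }
    return GeneticMap(anchors)


def write_genetic_map(gmap: GeneticMap, path: str | Path) -> None:
    rows = []
    for chrom, (bp, cm) in gmap.anchors.items():
        for b, c in zip(bp, cm):
            rows.append((chrom, int(b), float(c)))
    pd.DataFrame(rows, columns=["chrom", "pos_bp", "cM"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene annotation (BED)
# ---------------------------------------------------------------------------

GENE_COLUMNS = ["gene_id", "chrom", "start_bp", "end_bp", "is_candidate"]


def read_gene_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3+name gene intervals into 1-based inclusive coordinates."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    if df.shape[1] < 4:
        raise HapIOError("gene BED needs at least 4 columns (chrom, start, end, name)")
    out = pd.DataFrame(
        {
            "gene_id": df.iloc[:, 3].astype(str),
            "chrom": df.iloc[:, 0].astype(str),
            "start_bp": df.iloc[:, 1].astype(np.int64) + 1,
            "end_bp": df.iloc[:, 2].astype(np.int64),
            "is_candidate": False,
        }
    )
    if (out["end_bp"] < out["start_bp"]).any():
        bad = out[out["end_bp"] < out["start_bp"]].iloc[0]
        raise HapIOError(f"zero/negative-length BED interval for {bad.gene_id}")
    if out["gene_id"].duplicated().any():
        dup = out.loc[out["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise HapIOError(f"duplicate gene_id {dup!r} in BED")
    return out.reset_index(drop=True)


def write_gene_bed(genes: pd.DataFrame, path: str | Path) -> None:
    bed = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": genes["start_bp"] - 1,
            "end": genes["end_bp"],
            "name": genes["gene_id"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    population_label: str
    n_snps_in: int
    n_individuals_in: int
    n_snps_missing_removed: int
    n_individuals_removed: int
    n_snps_maf_removed: int
    n_snps_out: int
    n_individuals_out: int
    snp_missing_max: float
    ind_missing_max: float
    maf_min: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(self)])


def qc_filter(
    hap: HaplotypeMatrix,
    snp_missing_max: float = 0.02,
    ind_missing_max: float = 0.05,
    maf_min: float = 0.01,
) -> tuple[HaplotypeMatrix, QCReport]:
    """Cohort QC in a fixed order: SNP missingness, individual missingness,
    then MAF recomputed on the retained individuals.

    Removal is strict: a SNP goes when its genotype missingness exceeds
    ``snp_missing_max``, an individual when their missingness exceeds
    ``ind_missing_max``, and a SNP when its minor-allele frequency falls
    below ``maf_min``.
    """
    for name, t in (
        ("snp_missing_max", snp_missing_max),
        ("ind_missing_max", ind_missing_max),
        ("maf_min", maf_min),
    ):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {t}")

    n_snps_in, n_ind_in = hap.n_variants, hap.n_individuals

    keep_snp = hap.snp_missing_rate() <= snp_missing_max
    step1 = hap.subset_variants(np.flatnonzero(keep_snp))
    n_snp_missing_removed = int((~keep_snp).sum())
    if step1.n_variants == 0:
        raise HapIOError("QC removed every SNP at the missingness step")

    keep_ind = step1.individual_missing_rate() <= ind_missing_max
    step2 = step1.subset_individuals(np.flatnonzero(keep_ind))
    n_ind_removed = int((~keep_ind).sum())
    if step2.n_individuals == 0:
        raise HapIOError("QC removed every individual")

    maf = step2.maf()
    keep_maf = np.isfinite(maf) & (maf >= maf_min)
    step3 = step2.subset_variants(np.flatnonzero(keep_maf))
    n_maf_removed = int((~keep_maf).sum())
    if step3.n_variants == 0:
        raise HapIOError("QC removed every SNP at the MAF step")
    step3.refresh_variant_stats()

    report = QCReport(
        population_label=hap.population_label,
        n_snps_in=n_snps_in,
        n_individuals_in=n_ind_in,
        n_snps_missing_removed=n_snp_missing_removed,
        n_individuals_removed=n_ind_removed,
        n_snps_maf_removed=n_maf_removed,
        n_snps_out=step3.n_variants,
        n_individuals_out=step3.n_individuals,
        snp_missing_max=snp_missing_max,
        ind_missing_max=ind_missing_max,
        maf_min=maf_min,
    )
    return step3, report


def intersect_variants(haps: dict[str, HaplotypeMatrix]) -> dict[str, HaplotypeMatrix]:
    """Restrict every population to the variants present in all of them.

    Frequency contrasts (Fst, differentiation LRT) need the same loci in
    every population; per-population QC can drop different SNPs.
    """
    keys = [h.variant_key() for h in haps.values()]
    common = keys[0]
    for k in keys[1:]:
        # sort=False keeps genomic order (string sort would scramble positions)
        common = common.intersection(k, sort=False)
    out = {}
    for (label, hap), key in zip(haps.items(), keys):
        idx = key.get_indexer(common)
        out[label] = hap.subset_variants(idx)
    return out
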