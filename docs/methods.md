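# Methods

`sweepscan` detects footprints of recent positive selection in phased,
multi-population SNP data by combining two complementary per-SNP signals —
extended-haplotype homozygosity and allele-frequency differentiation — into
gene-level scores, and then asks whether a candidate gene set carries an
excess of those signals relative to matched controls.  This note documents
the statistical model behind each stage, the tunable parameters and their
defaults, what the bundled simulator does and does not emulate, and the
numerical choices and known limitations.

## Per-SNP statistics

### Extended haplotype homozygosity and iHS

For a focal SNP and an allele class (ancestral or derived), EHH(x) is the
probability that two randomly drawn carrier haplotypes are identical at
every SNP between the focal SNP and position x.  The implementation refines
haplotype group labels marker-by-marker outward from the focal SNP;
EHH = Σ_g C(k_g, 2) / C(n, 2) over groups g of identical haplotypes, so
EHH starts at 1 and is non-increasing in distance.  A haplotype with a
missing allele anywhere in the extended interval is treated as
non-homozygous with every other haplotype from that point on — a
conservative choice that can only shrink EHH.

The curve stops when EHH drops below `ehh_cutoff` (default 0.05), when the
chromosome ends, or when an inter-marker gap exceeds `max_gap_bp` (default
200 kb).  Curves stopped by an edge or gap are flagged truncated and
excluded from iHS by default (`keep_truncated` retains them): a truncated
integral underestimates iHH by an unknown amount.

iHH is the trapezoidal integral of max(EHH − cutoff, 0) against genetic
position (cM; physical distance at 1 cM/Mb stands in when no map is given),
summed over both sides.  The unstandardized score is ln(iHH_A / iHH_D); a
sweeping derived allele drags a long homozygous haplotype, inflating iHH_D
and driving the score negative.  Because haplotype lengths depend strongly
on allele frequency, raw scores are standardized within derived-allele
frequency bins of width `bin_width` (default 0.025, population-SD
convention), yielding scores with mean 0 and SD 1 within each bin.  Focal
SNPs require a derived frequency in [0.05, 0.95] and at least two carriers
of each allele; both bounds are configurable.  These are the conventional
defaults of EHH-based scan software, adopted here because no stronger
domain argument overrides them.

### Differentiation LRT on a drift tree

Three populations — a target, a regional (South-American-like) reference
and a global outgroup reference — are related by a star tree.  Under pure
drift, the observed sample frequency x_i in population i around an
ancestral frequency μ is approximately

    x_i ~ Normal(μ, c_i·μ(1−μ) + μ(1−μ)/n_i),

the Balding–Nichols drift variance plus binomial sampling noise for n_i
sampled alleles.  Branch parameters c_i are estimated genome-wide from the
three pairwise Hudson Fst values by additivity
(c_T = (Fst_T,R1 + Fst_T,R2 − Fst_R1,R2)/2, etc.), with negative solutions
clamped to 10⁻⁶ under a warning.  Hudson Fst uses the ratio-of-sums
(ratio-of-averages) estimator, which is robust to rare variants.

The null likelihood maximizes the three-term product over μ; the
alternative releases the tested (target) branch — its term is evaluated at
its own maximum density, i.e. at μ_T = x_T with variance
(c_T + 1/n_T)·x_T(1−x_T) — and refits μ on the two remaining populations.
LRT = 2(lnL_alt − lnL_null), clipped at 0.  Large values mean the target
frequency is more differentiated than genome-wide drift predicts.

Numerics: μ is optimized on [10⁻⁶, 1−10⁻⁶]; a 201-point coarse grid
brackets the optimum (guarding against flat/multimodal likelihoods near
fixation) before bounded scalar refinement; all variances are floored at
10⁻⁶.  The whole-dataset path vectorizes the same computation with
golden-section refinement and agrees with the scalar path to < 10⁻⁶; both
are tested against a dense μ-grid oracle.

A deliberate scale property of this construction, worth knowing when
interpreting fitted branch lengths: the Hudson estimator converges to the
*average* of the two branch drifts, (c_i + c_j)/2, not their sum, under the
Balding–Nichols parameterization used here (plus any shared founder-pool
drift; see the simulator section).  The additive-tree branch parameters are
therefore on the "pairwise-Fst" scale, roughly half the simulator's
Beta-parameterization c.  This affects the absolute LRT scale only; all
downstream inference is rank-based (empirical P-values), which is invariant
to a monotone rescaling of the statistic.

## Gene-level scores

SNPs are assigned to genes by position (1-based inclusive gene bodies,
optional `flank_bp`, default 0; a SNP inside two overlapping genes counts
for both).  Per gene, comparison and summary statistic (mean and median),
the summaries are s_|iHS| over |standardized iHS| (SNPs with undefined
scores omitted and counted) and s_LRT over defined LRT values; genes with
fewer than `min_snps` (default 1) defined scores carry explicit missing
values.

Each summary is converted to a right-tail empirical P-value against the
gene-level background distribution (default: all annotated genes,
candidates included; `exclude_candidates_from_background` flips that).
Genes that are themselves background members are ranked leave-self-out
(p = rank/N — exactly uniform on {1/N, …, 1} under the null); external
genes use the (1+r)/(1+N) convention.  Either way p > 0, so logs are safe.

The two P-values are combined with Fisher's statistic

    Z_F = −2(ln P_|iHS| + ln P_LRT),    Z_F ~ χ²₄ under the null,

and the χ²₄ survival function gives the gene's formal P-value.  With two
data-set configurations × two regional references × two summary statistics
the scan emits eight Z_F values per gene.  The χ²₄ null assumes the two
P-values are independent; |iHS| (haplotype structure) and LRT (frequency
differentiation) are nearly orthogonal signals, and the gene-level type-I
error on neutral simulations stays at the nominal rate (see README,
reproducing the results).

## Matched-control enrichment

Scan power per gene depends on local recombination rate and on the number
of SNPs analyzed, so a candidate set is compared against controls matched
on exactly those covariates: recombination rate in cM/Mb across the gene
interval (genes shorter than 1 kb use a 10 kb centered window) and assigned
SNP count.  For each candidate, the `k_pool` (default 1000) nearest
background genes by Euclidean distance on background-z-scored covariates
form its pool (ties broken lexicographically; candidates never enter
pools; a zero-variance covariate contributes nothing).  `n_sets` (default
1000) control sets draw one gene per pool uniformly at random (seeded;
within-set duplicates resolved by redrawing, hard failure after 100
attempts).  Signals are counted per rule — each comparison separately, and
"at least k" of the comparisons for k = 1, 2, 3 — as genes with
P(Z_F) < α (default 0.05, strict inequality).  The enrichment P-value is
(1 + #{control sets with count ≥ observed}) / (1 + n_sets); a strict ">"
variant is available.  Sampling from pools (rather than rank-assignment)
is used because it yields an exchangeable null.

On the bundled 200-gene synthetic fixture, `k_pool` must be smaller than
the background; pipeline examples use `k_pool = 50`.

## The synthetic-data generator

The simulator emulates array-genotyped, phased SNP data for one target and
two reference populations; it is the validation harness for every other
module, not a population-genetics simulator of record.

* **Map and positions.** Two chromosomes of 50 Mb; map anchors every 1 Mb
  with per-interval rates drawn log-normally (median 1 cM/Mb, σ_log = 0.5),
  giving genes a realistic spread of recombination rates; 5,000 uniformly
  placed SNP positions per chromosome.
* **Frequencies.** Ancestral frequency μ ~ Uniform(0.05, 0.95) per SNP
  (array-ascertained common variants), then per population
  x_i ~ Beta(μ(1−c_i)/c_i, (1−μ)(1−c_i)/c_i) — the Balding–Nichols model,
  E[x_i] = μ, Var[x_i] = c_i·μ(1−μ).  Default drift c = (0.02, 0.06, 0.10)
  for (target, regional reference, global reference) puts pairwise
  genome-wide Fst in the 0.08–0.13 range typical of closely to moderately
  diverged human populations.
* **Haplotypes and LD.** Per population, `founder_count` (default 20)
  founder haplotypes are drawn site-wise Bernoulli(x_i); each of the 2n
  sample haplotypes is a Li–Stephens-style mosaic over founders, switching
  with probability 1 − exp(−`switch_rate`·d_cM) between adjacent SNPs
  (default 2 switches/cM), restarting at chromosome boundaries.  Sharing of
  founder segments produces r² that decays with genetic distance.  Two
  consequences are intentional and documented: realized sample frequencies
  scatter around x_i with variance x(1−x)(1/F + (1−1/F)/2n) — founder-pool
  resampling adds to the binomial term — and the founder bottleneck
  contributes ≈ 1/F of additional drift shared by all populations, visible
  as an offset in genome-wide Fst.
* **Sweeps.** A hard sweep at a gene copies one derived-carrier haplotype
  (the sweeping lineage) over non-carrier haplotypes until the focal SNP
  reaches `final_freq`; each replacement covers a window of exponential
  half-length (mean 0.5/ln(1/(1−final_freq)) cM, configurable), so
  homozygosity decays away from the focal SNP.  The focal SNP is the gene
  SNP nearest the midpoint among those whose derived allele is rare
  (≤ 0.25) in *every* population — a hard sweep rises from a rare variant,
  and an allele already common in the references would carry no
  differentiation signal; the constraint relaxes to the target population,
  then to the rarest carrier SNP, when no SNP qualifies.  Automatic
  sweep-gene choice prefers genes holding such a SNP.  Ground truth
  (gene, focal position, realized final frequency, seed) is recorded.
* **Determinism.** All randomness flows from one `numpy` Generator seeded
  by `SimConfig.seed`; identical configs produce byte-identical output
  files.

What the generator does **not** emulate: demographic events (bottlenecks,
expansions, migration), soft sweeps or background selection, mutation-rate
or ascertainment heterogeneity, genotyping error, unphased or unpolarized
input, and realistic founder LD (founder haplotypes themselves are
site-wise independent).  Passing tests therefore demonstrate that the
statistics behave correctly under the stated drift + mosaic + hard-sweep
model — not that the pipeline's power or calibration transfers unchanged
to real cohort data.

## Known limitations

* Per-SNP sweep signal strength is bounded by the injection window scale:
  with the default exponential mean (0.217 cM at final frequency 0.9), two
  clone haplotypes share the sweeping lineage only over the intersection
  of their windows, halving the homozygosity scale.  Focal standardized
  iHS typically lands near −2 to −2.5 — strongly negative (the sign is
  negative in ≈ 98% of injected sweeps) but usually short of the extreme
  1% tail of the standardized distribution.  Detection is designed to work
  at the gene level, where several elevated SNPs plus the LRT combine; on
  default settings ≥ 90% of swept genes rank in the top 5% of gene
  P-values.
* Hudson Fst between two simulated populations estimates
  (c_eff_i + c_eff_j)/2 with c_eff = 1 − (1−c)(1−1/F), not c_i + c_j (see
  the drift-tree section); fitted tree branches inherit that scale.
* The enrichment null is discrete: with few candidates the attainable
  P-values are lumpy and the test is conservative; with a candidate set
  that is a large fraction of a small background, excluding candidates
  from pools couples the null to the observed count.  Both effects vanish
  in the regime the method targets (tens of candidates against a
  genome-wide background of thousands of genes).
* The QC module filters in a fixed order (SNP missingness → individual
  missingness → MAF recomputed on retained individuals); MAF uses the
  post-removal cohort by design, so borderline SNPs can change status when
  individuals are dropped.
* Ancestral-allele assignment is taken from the VCF `AA` INFO tag; the
  outgroup-major-allele fallback polarizer is provided but off by default,
  since mispolarization flips the sign of iHS at affected SNPs.
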