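# Methods

`methregions` re-implements, as a tested reusable pipeline, the
smoothing-based analysis of multi-tissue whole-genome bisulfite sequencing
(WGBS) data: differentially methylated region (DMR) and block calling with
permutation family-wise error control, variably methylated region (VMR)
detection with an SD-quantile cutoff and Cook's-distance outlier filtering,
and CpX-resolution genomic-feature enrichment.  A seeded synthetic-data
generator stands in for the raw multi-donor study data.

## Data model and coordinates

The analysis currency is a per-cytosine count matrix: methylated reads `M`
and total reads `Cov` over loci x samples, read from Bismark-style cytosine
reports (1-based positions).  CpG dinucleotides are palindromic, so +/−
strand counts of each CpG are summed onto the + strand C position before
analysis; CpA/CpT are not palindromic and are analysed per strand.  All
interval sets (features, BED I/O) are normalised internally to 0-based
half-open coordinates; a 1-based inclusive locus span `[s..e]` maps to
`[s-1, e)` exactly.  Zero-coverage loci are retained in datasets and
filtered per analysis, because the non-CpG analysis uses all loci
regardless of coverage.

## Smoothing

Methylation fractions are smoothed per sample with a BSmooth-style local
polynomial: at each locus a degree-2 polynomial of `M/Cov` against position
is fit by weighted least squares over a symmetric window, with weights
`tricube(distance / h) * Cov` and `h` one bp beyond the farthest window
member (so endpoints keep a small positive weight).  The window is the
smallest symmetric extension satisfying BOTH a minimum width and a minimum
locus count, truncated one-sidedly at chromosome ends.  Presets:

| preset     | min width | min loci | used for               |
|------------|-----------|----------|------------------------|
| `cg_small` | 1,000 bp  | 70       | CG-DMRs, VMR input     |
| `cg_block` | 20,000 bp | 500      | long low-amplitude blocks |
| `ch`       | 3,000 bp  | 200      | CpA/CpT strata         |

The 70/500/200 locus minima and the 20-kb/3-kb widths are the published
window constraints of the method family; the 1-kb small-window width is the
smoother's own default (at realistic CpG densities the locus-count
constraint dominates, so this choice is inert).  Degree and kernel are
configurable; coverage-proportional weighting is used throughout (a
variance-stabilised alternative was considered and not adopted, for
testability against a plain WLS oracle).  A locus whose whole window has
zero coverage for a sample is missing (NaN) and excluded locus-wise
downstream.  Fits are evaluated at the locus and clamped to [0, 1].  The
production path is a numba-jitted kernel; a vectorised numpy implementation
of the identical computation is kept as the fallback and as the reference
in tests (the two agree to ~1e-8).

## DMR calling and FWER control

Per locus, a one-way ANOVA F statistic across groups is computed on
smoothed values (missing values excluded; for two groups the signed
pooled-variance t is used, with F = t²).  Loci where any group has fewer
than two non-missing samples are missing; loci with zero within-group
variance but non-zero between-group variance receive an infinite statistic
that is capped at the finite maximum before segmentation so region scores
stay finite.

Candidate regions are maximal runs of loci with statistic at or above a
cutoff (two-group mode: |t| above cutoff with constant sign), split at
chromosome changes and at inter-locus gaps above `max_gap_bp` (defaults
300 bp for CG-DMRs, 10 kb for blocks, 1 kb for CH), discarding runs shorter
than `min_loci` (default 3).  Regions carry `areaStat` (sum of locus
statistics), `maxStat`, per-group means, and the maximal pairwise group
difference.

The default cutoff is the genome-wide 0.95 quantile of the locus statistic.
The extreme-5% convention matches the BSmooth family default (two-sided
`qcutoff` (0.025, 0.975)); a stricter quantile was tried first and proved
fragile — once planted (or real) signal occupies more than a few percent of
loci, a 0.99 quantile rides on the signal itself and misses moderate-effect
DMRs.  The cutoff is user-overridable, and when quantile-based it is
re-derived inside each permutation so the identical procedure is applied to
permuted data.

Family-wise error control is maxT-style: B permutations of the group
labels (uniform over assignments; samples are donor-unique per tissue), the
full statistic + segmentation pipeline re-run per permutation, and the
maximum |areaStat| recorded.  Each observed region gets the add-one
estimator `fwer_p = (1 + #{perm maxima >= |areaStat|}) / (B + 1)`; regions
with `fwer_p <= alpha` (default 0.05) are flagged significant.  For tiny
designs an exhaustive mode enumerates all distinct non-identity label
assignments.  Permutation seeds are mandatory.

Pairwise annotation marks a region with every group pair whose region-mean
methylation differs by at least `delta_min` (default 0.1).  A region is
*discriminatory* for group g when every annotated pair contains g;
per-group discriminatory sets are ranked by `maxStat` and optionally
capped.  The CH pipeline is the same machinery run once per
dinucleotide/strand stratum (CA+/CA−/CT+/CT−; CC supported but off by
default) with the `ch` preset, reporting the union of the per-stratum sets.

## VMR calling

Loci are first filtered to those with coverage strictly above `min_cov`
reads in strictly more than `min_samples` samples (mirroring the "> 5 reads
in > 100 samples" rule; `min_samples` defaults to half the cohort to scale
with design size).  Per tissue, the per-locus sample SD (n−1 denominator)
of smoothed values is computed; the genome-wide cutoff is the minimum
across tissues of each tissue's 0.99 SD quantile (type-7 interpolation —
quantile definitions matter at the 99th percentile).  Using one cutoff for
all tissues lets more-variable tissues yield more VMRs.  At the reference
cutoff 0.095 the +/−2 SD span is 4 x 0.095 = 0.38, i.e. a 38% methylation
difference.

VMRs are maximal runs of loci with SD strictly above the cutoff (gap rule
as for DMRs, default 300 bp), kept when they contain more than 10 CpGs.
Each VMR is then screened for single-sample artefacts: with per-sample
region-mean methylation `y_i` and an intercept-only fit (the minimal model
for "sample outlier relative to the tissue mean"; the original analysis
names no model), Cook's distance is `D_i = e_i² h / (p s² (1−h)²)` with
`h = 1/n`, `p = 1`, `s²` the residual mean square; the VMR is removed when
`max_i D_i > 0.7`.  All-equal means give D = 0 (retained); fewer than three
usable samples is degenerate and the VMR is rejected with a diagnostic.
The filter sentence in the source analysis is ambiguous; it is read as
*removing* high-Cook's VMRs because its stated purpose is removing
outlier-driven regions.  Effect size is the range of per-sample region
means.  SDs are computed on smoothed values (the analysis currency);
raw-fraction SD is available behind a flag.

Sharing classification union-merges retained VMRs across tissues (overlap
is >= 1 shared bp with transitive closure — the published "unique VMR"
count implies a union but not its overlap rule): a merged interval is
`tissue_specific` (one member tissue), `ubiquitous` (every configured
tissue), else `shared`; the classes partition the merged intervals.

## Enrichment

Enrichment of a region set in a genomic feature is computed at CpX
resolution: every locus of the relevant context is classified by region
membership and feature membership (point-in-interval on the C position),
giving a 2x2 table.  `log2(OR) = log2 n11 + log2 n22 − log2 n12 − log2 n21`,
`se = sqrt(1/n11 + 1/n12 + 1/n21 + 1/n22)`, 95% CI `log2(OR) -/+ 2 se`, and
a two-sided Fisher exact p-value.  No continuity correction is applied: a
zero cell flags the result undefined (a Haldane +0.5 variant exists behind
an explicit flag).  Batch mode reports one row per feature with
Benjamini–Hochberg significance across features within a region set
(multiplicity handling for enrichment panels is this package's choice) and
can average `log2(OR)` within named feature groups (e.g. one chromatin
state across several reference tissues); significance is never averaged.

## Synthetic data

The generator emulates a 5-tissue-group, multi-donor WGBS design on a
desk-scale genome (default two 2-Mb chromosomes, ~20,000 CpG sites →
~40,000 per-strand CG loci).

* **CpG placement** — an open-sea Poisson process (mean spacing 110 bp,
  matching genome-wide CpG density of roughly one per 107 bp) plus ~25
  dense islands per Mb (mean 30 CpGs at 15-bp spacing).
* **Baseline landscape** — bimodal: islands ~0.10, open sea ~0.85, with
  per-locus jitter (SD 0.03).
* **Emission** — per strand, coverage ~ Poisson(lambda/2) (lambda = 12,
  the ">10x post-processing" scale) and methylated counts beta-binomial
  with ambient dispersion rho = 0.02; the Beta draw is made once per
  (site, sample) and shared by both strands, so strand collapsing is
  consistent with one underlying cell population.
* **Planted DMRs** — 20 runs of 12–30 CpGs with group mean shifts of
  0.3–0.5 (sign away from the nearer boundary); **blocks** — 4 runs of
  300–600 CpGs with shifts of 0.08–0.12.
* **Planted VMRs** — 20 runs of 15–30 CpGs; per-sample level shifts
  b_s ~ Normal(0, 0.15²) drawn once per (sample, region) — variability is
  regional, matching the region-level SD definition.  Affected-tissue sets
  mix tissue-specific, partially shared, and fully shared regions.  VMR
  regions are re-based to an intermediate methylation level (U(0.35,
  0.65)): real VMRs sit at intermediate methylation, and without this the
  [0, 1] clamp at an extreme baseline skews per-sample means and makes the
  lowest sample look like a Cook's outlier in every tissue.
* **Genotype-driven VMRs** — a biallelic SNP per region (MAF 0.3, allele
  effect 0.35 per copy) with genotypes drawn per donor, producing trimodal
  per-sample means; labelled `snp_vmr` in the truth set.
* **Outlier VMRs** — regions whose variability comes solely from one
  sample shifted by 0.6, the pseudo-VMRs the Cook's filter must remove.
* **CH strata** — CA+ and CA− simulated sparsely (a quarter of CpG
  density) at baseline 0.03 with planted elevations of 0.08–0.12 (CT/CC by
  flag).
* Planted DMR/VMR runs are placed in locally CpG-dense stretches (internal
  gaps <= 250 bp), mirroring the concentration of real regulatory-scale
  regions in CpG-dense sequence; otherwise an exponential-spacing landscape
  splits planted runs across the callers' gap rule and recovery tests
  measure placement luck rather than detection.

The default design uses **8 samples per tissue**.  The Cook's 0.7
threshold was calibrated in a study with 12–23 donors per tissue; the null
probability that the max Cook's distance of i.i.d. normal per-sample
shifts exceeds 0.7 is 0.39 at n = 5 but 0.076 at n = 8 and ~0.002 at study
scale, so 5-donor designs destroy genuine VMRs wholesale while 8 (the top
of the realistic desk-scale range) preserves the filter's intent.  The
null-calibration experiment for the DMR caller uses its own pinned
5 groups x 5 samples design.

What the generator does **not** emulate: read-level data (no FASTQ/BAM),
sequence context beyond spacing statistics, spatially correlated ambient
variability (metastable-epiallele background), donor effects shared across
tissues other than planted SNPs, or chromosome-scale features
(centromeres, CNVs).  Passing recovery tests therefore demonstrate correct
statistics and segmentation under the declared noise model, not
performance on real tissue heterogeneity.

## Numerical choices

* Locus statistics use exact-zero detection with a relative tolerance of
  1e-12 on the total sum of squares; SSW = SSB = 0 gives F = 0, SSW = 0
  with SSB > 0 gives +inf (capped before segmentation).
* Smoothing windows with fewer covered loci than polynomial coefficients
  fall back to the coverage-weighted window mean; zero covered loci give a
  missing value.
* Permutation p-values use the add-one estimator, so p >= 1/(B+1) > 0.
* Quantiles are numpy type-7 (linear interpolation) throughout.
* The large gathered tensors in the fallback numpy smoother are single
  precision; moment sums over a few hundred bounded weights keep ~6–7
  significant digits, and the jitted path is double precision.

## Experiment sizes

The bundled experiments are sized for a single CPU: the FWER calibration
runs 200 null replicates at B = 50 permutations (~8 minutes); recovery runs
pool 3 (DMR) and 6 (VMR) standard-configuration replicates; the outlier
removal rate uses 40 small single-chromosome replicates; the enrichment
null-centering check uses 200 random placements.

## Known limitations

* No locus-wise variance moderation (bsseq-style shrinkage): plain ANOVA
  on smoothed values.  On low-replicate designs this is slightly
  conservative after permutation control.
* The permutation scheme ignores donor structure (samples are
  donor-unique per tissue in the emulated design).
* CH analyses default to CA strata only at desk scale; CT/CC are
  supported but enlarge fixtures considerably.
* `Fisher` p-values come from SciPy's exact routine; for margins beyond
  the exact-enumeration test range the usual conditional-exact caveats
  apply.
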