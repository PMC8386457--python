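# Methods

## Scope and data model

The package starts where an aligner stops: per-sample tables assigning
reads to reference sequences, where each reference is either a bacterial
SSU-rRNA OTU (with a rank lineage) or a genomic HLA sequence (gene plus
two-digit allele group). Everything downstream — genotype calling,
presented-peptidome similarity, diversity, stratified testing — operates
on these tables or on objects derived from them, so the pipeline never
needs raw reads, SAM/BAM files, or an external binding predictor binary.

## Multimapper apportionment and filtering

A read aligning to a single reference contributes 1 to that reference.
A multimapping read is divided across its targets in proportion to each
target's unique-read count; when none of its targets has unique support
the read is split equally (the proportional rule is undefined at 0/0 and
the equal split preserves the total). Apportionment is a single
proportional pass, not an EM iteration. Per-read fractions sum to 1, so
the grand total equals the number of distinct reads — asserted to 1e-9
in the tests.

OTU tables are filtered by two inclusive thresholds: samples need a
total SSU count of at least `min_reads` (default 1000) and, within a
retained sample, an OTU needs relative abundance of at least
`min_rel_abund` (default 1e-4). The relative-abundance denominator is
the sample's pre-filter total, which makes the threshold independent of
filter order; the pre-filter totals are carried on the table because
they are also the N of Margalef richness. Re-filtering a filtered table
with its stored totals is a no-op.

## Genotype calling

For each gene, alleles are ranked by read count with ties broken by
allele name (determinism; the ordering choice is otherwise arbitrary).
The R score is (c₁+c₂)/Σothers, ∞ when only the top two alleles carry
reads, 0 when the gene has no reads. A gene is not called when R <
`r_min` (default 2) or the top allele has fewer than `min_top_reads`
(default 10) reads; the depth floor is applied before the zygosity split
for both homozygous and heterozygous outcomes, keeping no-call semantics
uniform (the published rule states the floor only for the homozygous
branch; extending it to heterozygotes is the conservative reading). At
or above `het_fraction` (default 0.15) of the top allele's reads the
second allele makes the call heterozygous; strictly below, homozygous —
the boundary itself is heterozygous. The R gate is checked before the
depth gate; with both as preconditions the order does not affect the
call set.

Replicate consistency takes the most frequent called genotype per gene
as consensus (first-encountered wins ties, in input order) and reports
the fraction of per-replicate calls matching the consensus alleles and
zygosity. Population-level quality control correlates cohort allele
frequencies (homozygotes counted twice) against a user-supplied
reference table over the union of alleles, reporting Pearson r per gene
and NaN when fewer than three allele categories or zero variance make
the correlation meaningless.

## Peptidome and PPSS

The peptidome is sampled by enumerating all 9-mer windows of the input
proteins and keeping each candidate independently with probability
`sample_rate` (default 1/1000), deduplicating afterwards; windows with
non-canonical residues are skipped. Bernoulli sampling, rather than a
strided 1-of-1000, is the natural reading of random inclusion and keeps
windows independent.

A binding predictor is any deterministic callable mapping (allele,
peptide) to a percentile rank; peptides at or below `rank_cutoff`
(default 2.0 %Rank, the cutoff convention of standard MHC-I predictors)
form the allele's presented set. Allele similarity is the Jaccard index
of presented sets, with the empty-vs-empty case defined as 0 (avoids
0/0 and keeps scores conservative). PPSS sums the 2×2 allele-pair
Jaccard values per class I gene over HLA-A, -B and -C; a homozygous gene
enters with its allele duplicated, so it contributes four copies of its
J values — implied by the 2×2 sum, and worth noting because it doubles
the weight of homozygous loci. Class II genes are typed but not scored;
peptide presentation by class II molecules is too promiscuous for the
same construction to be meaningful. PPSS can be computed from raw sets
or from a precomputed allele-pair Jaccard table; the two routes agree to
1e-12 and the table route is the format users with published J tables
will take.

## Diversity

Margalef richness (S−1)/ln N and Heip evenness (e^H−1)/(S−1) use S =
OTUs with positive filtered abundance and N = pre-filter mapped SSU
reads; H is the natural-log Shannon–Wiener entropy. N < 2 and S < 2
respectively are reported as NaN rather than raised. No rarefaction is
performed. Spearman beta similarity aligns each pair on the union of
their observed OTUs with zeros for absences (defined for every pair;
the intersection variant would discard exactly the discordant OTUs that
carry signal). Weighted UniFrac runs on a taxonomy tree expanded from
rank lineages with every branch length 1; the raw (non-normalized) form
Σ|A_b−B_b| is used. An all-pairs fast path rank-transforms the table
once and takes matrix correlations; it is exact whenever no OTU is
absent from both members of a pair and the per-pair path is used
otherwise.

## Stratified KS comparisons

Pairs are binned by PPSS with left-closed edges (default <4, [4,6),
[6,8), ≥8), by shared-allele count (multiset intersection of genotypes,
0–6), or by shared HLA-A/B supertypes; samples are grouped by number of
heterozygous genes or by which gene is homozygous (a sample homozygous
at several genes appears in each of those strata). The two-sample KS
test uses the exact P value when n₁·n₂ ≤ 10,000 and the asymptotic form
above that. The heatmap cell (row, column) tests the null that the row
stratum is drawn from an equal-or-smaller distribution than the column
stratum; diagonals are defined as 1, strata with fewer than two values
give NaN. The `alternative` argument follows the stochastic-ordering
reading ("greater" = first sample stochastically greater), which maps to
the reversed CDF-based convention of `scipy.stats.ks_2samp`.

Pairwise beta-diversity values are not independent observations — pairs
share samples — and the KS test is applied to them anyway, because that
is the analysis this package implements. P values on real, strongly
structured communities should be read with that caveat (see below).

## Synthetic cohorts

The generator produces every input with known truth from one seed via
named substreams (haplotypes, reads, presentation, baseline,
microbiota), so stages regenerate independently.

- **Haplotypes**: two alleles per gene drawn independently from the
  gene's frequency pool (Hardy–Weinberg, no linkage). Default pools
  hold 8 alleles per gene with skewed frequencies (0.30 … 0.04).
- **Reads**: per-gene depth is gamma-Poisson with mean `depth_mean`
  (default 200, comfortably above the 10-read floor) and dispersion 2;
  reads split evenly between the two true alleles and each leaks to a
  uniformly random other allele of the gene with probability
  `cross_mapping_rate` (default 0.02), emulating cross-allele mapping.
- **Presentation**: per-allele synthetic 9-mer sets of equal size m
  realize a target pairwise Jaccard kernel. The default hierarchical
  kernel (two binding families per gene, J = 0.6 within a family, 0.1
  across) is built exactly from nested cores — a gene-wide core, a
  family core, private peptides — using O = 2mJ/(1+J). Explicit
  pairwise kernels use one dedicated block per pair and raise when an
  allele's requested overlaps exceed its set size. The family structure
  mirrors the supertype-like block structure of real allele-pair J
  tables and gives cohorts a broad PPSS spread.
- **Microbiota**: each OTU's typical abundance comes from a shared
  log-normal baseline (spread `baseline_sigma`); every class I allele
  of an individual suppresses the OTUs its presented peptides hash to,
  by a factor e^(−effect_size) per suppressing allele slot; per-sample
  log-normal noise (`noise_sd`) is applied and rows are scaled to a
  fixed depth. Individuals with overlapping presented peptidomes share
  suppression patterns, so community similarity rises with PPSS;
  `effect_size = 0` yields exchangeable communities.

### The baseline/noise operating point

The defaults are `baseline_sigma = 0.1` and `noise_sd = 1.0`, and the
choice is deliberate. With a strongly uneven shared baseline every
sample's rank profile tracks the baseline to a sample-specific degree;
that acts as a cluster-level random effect on pairwise Spearman values,
and because PPSS strata also group pairs by sample, the stratified KS
null becomes sharply anti-conservative (a quarter of null cohorts
rejecting at 0.05, independent of the number of OTUs). The generator's
contract is that a zero-effect cohort is an exchangeable null on which
the stratified comparison is calibrated, so the baseline spread is kept
small enough for per-sample noise to dominate the ranks: at the default
operating point the null rejection rate of the top-vs-bottom PPSS
comparison is ~7% over 200 cohorts and the planted effect
(effect_size 1.0, n = 60) is recovered in 100/100 cohorts.

The flip side is a real limitation: synthetic communities are far more
even than real gut communities, whose abundances span orders of
magnitude. Passing null calibration here shows the statistical
machinery is correct on exchangeable inputs; it does not certify
calibration on real data, where the shared community structure
reintroduces exactly the dependence described above and the
dependent-pairs caveat applies in full.

Other things the generator does not emulate: read-level sequences
(counts only), 16S copy-number variation, linkage disequilibrium
between HLA loci, population stratification, and alignment-score-aware
multimapping.

## Problem sizes and numerical choices

Simulation-based tests use cohorts of 60 individuals (200 for typing
recovery), 150 OTUs and ~100 peptides per allele, with 100 replicate
cohorts for the calibration/power checks — sizes at which every
distributional property under test is already stable. Exact closed-form
checks (PPSS bounds, diversity identities, conservation) are asserted
at 1e-12 to 1e-9. Degenerate inputs are values, not crashes: empty
gene counts give R = 0 and no_call, undefined indices give NaN,
empty-set Jaccard gives 0, and an empty filtered OTU table is an empty
table.
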