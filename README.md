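# hlabiome

Host genetics meets the gut microbiome: this package asks whether people
with functionally similar HLA (human leukocyte antigen) molecules carry
similar gut bacterial communities, and provides every step needed to
answer it from shotgun-metagenome read counts — HLA genotyping, a
functional HLA similarity score, microbiota diversity, and stratified
distribution tests — together with a synthetic-cohort generator with
known ground truth for validating the whole chain.

It is aimed at microbiome researchers who have mapped gut shotgun reads
against a composite reference (bacterial SSU rRNA plus genomic HLA
sequences) and want a tested, reusable implementation of the downstream
analysis.

## The method

**HLA typing from read counts.** HLA alleles of one gene are nearly
identical, so reads smear across alleles. For each gene the *R* score is

&nbsp;&nbsp;&nbsp;&nbsp;R = (c₁ + c₂) / Σ other allele counts,

the reads on the two most frequent alleles over the reads on all other
alleles of the gene. A gene is typed only when R ≥ 2 and the top allele
has ≥ 10 reads; it is called homozygous when the second allele has
< 15% of the top allele's reads and heterozygous at or above 15%.

**Presented peptidome similarity (PPSS).** A gut peptidome is sampled by
sliding a 9-residue window over bacterial proteins and keeping one
candidate in a thousand. A binding predictor (pluggable; ≤ 2.0 %Rank
counts as presented) turns it into a presented-peptide set P_a per
allele. Allele similarity is the Jaccard index

&nbsp;&nbsp;&nbsp;&nbsp;J_ab = O_ab / (P_a + P_b − O_ab),

and the similarity of two individuals *i*, *j* is

&nbsp;&nbsp;&nbsp;&nbsp;PPSS_ij = Σ_{g∈{A,B,C}} Σ_{a_i=1,2} Σ_{a_j=1,2} J_{g,a_i,a_j},

which runs from 0 (no overlap) to 12 (identical presented peptidomes).

**Diversity and stratified tests.** Alpha diversity uses Margalef
richness D_mg = (S−1)/ln N and Heip evenness E = (e^H−1)/(S−1); beta
diversity uses Spearman rank correlation of OTU abundances and raw
weighted UniFrac on a taxonomy tree with unit branch lengths. Sample
pairs are stratified (by PPSS bin, shared alleles, or zygosity) and
strata are compared with one- and two-sided two-sample
Kolmogorov–Smirnov tests, reported as P-value heatmaps.

## Worked example

A synthetic cohort with a planted PPSS→similarity effect, typed and
analysed end to end:

```python
from hlabiome import (CohortSpec, simulate_cohort, call_profiles,
                      select_complete_profiles, ppss_matrix, pairwise_spearman,
                      bin_by_ppss, stratum_pvalue_heatmap)

spec = CohortSpec(seed=42, n_individuals=40, effect_size=1.0)
cohort = simulate_cohort(spec)

profiles = call_profiles(cohort.gene_counts)
complete = select_complete_profiles(profiles, hla_class=1)
print(f"class I complete: {len(complete)}/{len(profiles)}")

ppss = ppss_matrix(complete, cohort.pmap.to_table())
beta = pairwise_spearman(cohort.otu_table)
strata = bin_by_ppss(ppss, beta)
print(strata.groupby("stratum", observed=False)["value"].agg(["count", "median"]).round(3))
print(stratum_pvalue_heatmap(strata, alternative="greater").round(4))
```

prints

```
class I complete: 39/40
         count  median
stratum
<4          55   0.289
4-6        358   0.495
6-8        270   0.585
>=8         58   0.664
      <4  4-6  6-8  >=8
<4   1.0  1.0  1.0  1.0
4-6  0.0  1.0  1.0  1.0
6-8  0.0  0.0  1.0  1.0
>=8  0.0  0.0  0.0  1.0
```

39 of 40 individuals type completely; the median microbiota rank
correlation of a sample pair climbs from 0.29 (PPSS < 4) to 0.66
(PPSS ≥ 8); and each cell of the heatmap tests whether the row stratum's
similarity values are drawn from an equal-or-smaller distribution than
the column's — the zeros below the diagonal say every higher-PPSS
stratum is detectably more similar, exactly the planted effect.

The same stages are available as a CLI:

```sh
hlabiome --seed 42 simulate --n 40 --outdir sim/
hlabiome type-hla --counts sim/hla_counts.tsv --out profiles.tsv
hlabiome ppss --profiles profiles.tsv --presentation sim/presentation.tsv --out ppss.tsv
hlabiome diversity --otu sim/otu.tsv --lineages sim/lineages.tsv \
    --out-alpha alpha.tsv --out-beta beta.tsv
```

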