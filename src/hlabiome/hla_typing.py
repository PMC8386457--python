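"""Two-digit HLA genotype calling from allele read-count profiles.

Because HLA alleles of one gene are highly similar, reads map across
alleles and more than two alleles typically collect reads.  Calling is
gated by the R score — the reads on the two most frequently observed
alleles of a gene divided by the reads on all its other alleles — and by
a depth floor on the top allele.  A gene passing both gates is called
homozygous when the second allele has less than ``het_fraction`` (15%)
of the top allele's reads and heterozygous when it has at least that
fraction.  The module also provides cohort-level quality-control
operations: complete-profile selection per HLA class, consistency of
calls across replicate samples of one individual, and comparison of
cohort allele frequencies against a population reference.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .config import CLASS_I_GENES, CLASS_II_GENES, logger
from .read_assignment import GeneReadCounts


@dataclass
class GenotypeCall:
    """Genotype of one gene: zero, one or two called alleles plus zygosity."""

    gene: str
    status: str = "no_call"  # "called" | "no_call"
    allele1: str | None = None
    allele2: str | None = None
    zygosity: str = "undetermined"  # "hom" | "het" | "undetermined"
    r_score: float = 0.0

    @property
    def alleles(self) -> tuple[str, ...]:
        """Called alleles as a 2-multiset (homozygote = allele twice)."""
        if self.status != "called":
            return ()
        return (self.allele1, self.allele1) if self.zygosity == "hom" else (self.allele1, self.allele2)


@dataclass
class HlaProfile:
    """All six per-gene calls of one sample, with per-class completeness."""

    sample_id: str
    calls: dict[str, GenotypeCall] = field(default_factory=dict)

    def is_complete(self, hla_class: int) -> bool:
        genes = CLASS_I_GENES if hla_class == 1 else CLASS_II_GENES
        return all(g in self.calls and self.calls[g].status == "called" for g in genes)

    @property
    def class1_complete(self) -> bool:
        return self.is_complete(1)

    @property
    def class2_complete(self) -> bool:
        return self.is_complete(2)


def _ranked_alleles(counts: dict[str, float]) -> list[tuple[str, float]]:
    # deterministic: count descending, then allele name ascending
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def compute_r_score(counts: GeneReadCounts | dict[str, float]) -> float:
    """R score: reads on the top-two alleles over reads on all other alleles.

    Returns ``inf`` when only the top-two alleles carry reads, and 0 when
    the gene has no reads at all.  Ties are broken by allele name so the
    score is deterministic.
    """
    d = counts.counts if isinstance(counts, GeneReadCounts) else counts
    ranked = _ranked_alleles(d)
    if not ranked or sum(c for _, c in ranked) == 0:
        return 0.0
    top_two = sum(c for _, c in ranked[:2])
    others = sum(c for _, c in ranked[2:])
    if others == 0:
        return math.inf if top_two > 0 else 0.0
    return top_two / others


def call_genotype(
    counts: GeneReadCounts,
    r_min: float = 2.0,
    min_top_reads: float = 10,
    het_fraction: float = 0.15,
) -> GenotypeCall:
    """Apply the genotype decision tree to one gene's allele read counts.

    The gene is not called when its R score is below ``r_min`` or the top
    allele has fewer than ``min_top_reads`` reads.  Otherwise the call is
    heterozygous if the second allele has at least ``het_fraction`` of
    the top allele's reads (the boundary itself counts as heterozygous)
    and homozygous below that.  ``no_call`` is a value, not an error.
    """
    r = compute_r_score(counts)
    ranked = _ranked_alleles(counts.counts)
    call = GenotypeCall(gene=counts.gene, r_score=r)
    if not ranked:
        return call
    top_allele, top_count = ranked[0]
    if r < r_min or top_count < min_top_reads:
        return call
    second_count = ranked[1][1] if len(ranked) > 1 else 0.0
    call.status = "called"
    call.allele1 = top_allele
    if second_count >= het_fraction * top_count:
        call.zygosity = "het"
        call.allele2 = ranked[1][0]
    else:
        call.zygosity = "hom"
        call.allele2 = top_allele
    return call


def call_profiles(
    gene_counts: list[GeneReadCounts],
    r_min: float = 2.0,
    min_top_reads: float = 10,
    het_fraction: float = 0.15,
) -> list[HlaProfile]:
    """Call genotypes for every (sample, gene) and assemble per-sample profiles."""
    profiles: dict[str, HlaProfile] = {}
    for gc in gene_counts:
        prof = profiles.setdefault(gc.sample_id, HlaProfile(sample_id=gc.sample_id))
        prof.calls[gc.gene] = call_genotype(gc, r_min, min_top_reads, het_fraction)
    out = [profiles[s] for s in sorted(profiles)]
    n_c1 = sum(p.class1_complete for p in out)
    n_c2 = sum(p.class2_complete for p in out)
    logger.info("typed %d samples: %d class I complete, %d class II complete", len(out), n_c1, n_c2)
    return out


def select_complete_profiles(profiles: list[HlaProfile], hla_class: int) -> list[HlaProfile]:
    """Keep profiles whose three genes of the requested class are all called."""
    if hla_class not in (1, 2):
        raise ValueError("hla_class must be 1 or 2")
    return [p for p in profiles if p.is_complete(hla_class)]


def _genotype_key(call: GenotypeCall) -> tuple[tuple[str, ...], str]:
    return (tuple(sorted(call.alleles)), call.zygosity)


def replicate_consistency(
    replicate_calls: list[list[GenotypeCall]],
) -> tuple[float, float]:
    """Agreement of replicate samples of one individual with their consensus.

    The consensus genotype of a gene is the most frequent called genotype
    across replicates (first-encountered wins a tie).  Returns the
    fraction of per-replicate calls whose allele pair matches the
    consensus alleles, and the fraction whose zygosity matches the
    consensus zygosity.  Genes with no called replicate are skipped.
    """
    if len(replicate_calls) < 2:
        raise ValueError("need at least two replicates")
    genes = sorted({c.gene for calls in replicate_calls for c in calls})
    n_allele_ok = n_zyg_ok = n_total = 0
    for gene in genes:
        calls = [
            next((c for c in rep if c.gene == gene), None) for rep in replicate_calls
        ]
        called = [c for c in calls if c is not None and c.status == "called"]
        if not called:
            continue  # all replicates no_call for this gene
        keys = [_genotype_key(c) for c in called]
        tally = Counter(keys)
        best_n = max(tally.values())
        # first-encountered genotype wins a tie (stable order)
        cons_alleles, cons_zyg = next(k for k in keys if tally[k] == best_n)
        for c in called:
            n_total += 1
            n_allele_ok += tuple(sorted(c.alleles)) == cons_alleles
            n_zyg_ok += c.zygosity == cons_zyg
    if n_total == 0:
        raise ValueError("no called genes across replicates")
    return n_allele_ok / n_total, n_zyg_ok / n_total


def observed_allele_frequencies(profiles: list[HlaProfile], gene: str) -> dict[str, float]:
    """Allele frequencies over called genotypes (homozygotes counted twice)."""
    tally: Counter[str] = Counter()
    for p in profiles:
        call = p.calls.get(gene)
        if call is not None and call.status == "called":
            tally.update(call.alleles)
    total = sum(tally.values())
    return {a: n / total for a, n in sorted(tally.items())} if total else {}


def allele_frequency_comparison(
    profiles: list[HlaProfile],
    reference_freqs: dict[str, dict[str, float]],
) -> dict[str, float]:
    """Pearson r between cohort and reference allele frequencies, per gene.

    The correlation runs over the union of observed and reference alleles
    of a gene, with absent alleles at frequency 0.  Genes with fewer than
    three allele categories or zero variance on either side are reported
    as undefined (NaN).
    """
    out: dict[str, float] = {}
    for gene, ref in reference_freqs.items():
        obs = observed_allele_frequencies(profiles, gene)
        alleles = sorted(set(obs) | set(ref))
        if len(alleles) < 3:
            out[gene] = float("nan")
            continue
        x = np.array([obs.get(a, 0.0) for a in alleles])
        y = np.array([ref.get(a, 0.0) for a in alleles])
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            out[gene] = float("nan")
            continue
        out[gene] = float(stats.pearsonr(x, y).statistic)
    return out
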