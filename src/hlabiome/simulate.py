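"""Synthetic cohorts with known ground truth for every pipeline input.

The generator emulates the statistical structure the analysis assumes in
real gut-metagenome cohorts: HLA haplotypes drawn under Hardy–Weinberg
equilibrium from per-gene allele pools; per-gene read-count profiles
with cross-allele mapping leakage (alleles of one gene are so similar
that a fraction of a true allele's reads lands on other alleles);
per-allele presented-peptide sets whose pairwise Jaccard overlaps follow
a prescribed kernel (alleles within a binding family share a large core,
across families a small one); protein sequences for peptidome sampling;
and OTU abundance tables in which each presented peptide suppresses a
pseudo-random subset of taxa in its carriers, so that community
similarity between two individuals rises with their PPSS by a plantable
effect size (effect_size 0 gives exchangeable communities).

All randomness flows from a single cohort seed through named substreams,
so each stage can be regenerated independently and reproducibly.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CLASS_I_GENES, ALL_GENES
from .peptidome import AMINO_ACIDS, PresentationMap
from .read_assignment import GeneReadCounts, OtuTable


def _substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent random substream derived from the cohort seed."""
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


def _stable_hash(text: str) -> int:
    return zlib.crc32(text.encode())


@dataclass(frozen=True)
class HierarchicalKernel:
    """Target pairwise Jaccard structure for allele peptide sets of one gene.

    Alleles are split into ``n_families`` contiguous families; two
    distinct alleles of the same family share Jaccard ``within``, alleles
    of different families ``between`` (an allele with itself is 1).
    Feasible whenever ``between <= within <= 1``.
    """

    within: float = 0.6
    between: float = 0.1
    n_families: int = 2

    def family_of(self, alleles: list[str]) -> dict[str, int]:
        per = max(1, -(-len(alleles) // self.n_families))
        return {a: i // per for i, a in enumerate(sorted(alleles))}


def _default_pools() -> dict[str, dict[str, float]]:
    freqs = (0.30, 0.22, 0.15, 0.10, 0.08, 0.06, 0.05, 0.04)
    return {
        g: {f"{g}*{i + 1:02d}": f for i, f in enumerate(freqs)} for g in ALL_GENES
    }


@dataclass
class CohortSpec:
    """All knobs of a synthetic cohort; the seed is mandatory.

    Frequencies must sum to 1 within each gene pool.  ``effect_size``
    couples PPSS to community similarity (0 = no planted effect);
    ``cross_mapping_rate`` is the fraction of a true allele's reads
    leaking to other alleles of its gene.
    """

    seed: int
    n_individuals: int = 60
    allele_pools: dict[str, dict[str, float]] = field(default_factory=_default_pools)
    depth_mean: float = 200.0
    depth_dispersion: float = 2.0
    cross_mapping_rate: float = 0.02
    peptide_overlap_kernel: HierarchicalKernel | dict[tuple[str, str], float] = field(
        default_factory=HierarchicalKernel
    )
    n_otus: int = 150
    effect_size: float = 0.5
    noise_sd: float = 1.0
    # kept small so the per-sample noise dominates the ranks: a strongly
    # uneven shared baseline makes every sample's rank profile track it to a
    # sample-specific degree, which acts as a cluster-level random effect on
    # pairwise rank correlations and miscalibrates the stratified KS null
    baseline_sigma: float = 0.1
    sample_depth: float = 20_000.0

    def __post_init__(self) -> None:
        for gene, pool in self.allele_pools.items():
            total = sum(pool.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"allele frequencies of gene {gene} sum to {total}, not 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


def simulate_haplotypes(spec: CohortSpec) -> pd.DataFrame:
    """Draw a Hardy–Weinberg cohort: two independent alleles per gene.

    Returns the truth table with columns ``sample_id``, ``gene``,
    ``allele1``, ``allele2`` (sorted) and ``zygosity``.
    """
    rng = _substream(spec.seed, "haplotypes")
    rows = []
    for i in range(spec.n_individuals):
        sample_id = f"S{i:04d}"
        for gene, pool in spec.allele_pools.items():
            alleles = sorted(pool)
            probs = np.array([pool[a] for a in alleles])
            a1, a2 = sorted(str(a) for a in rng.choice(alleles, size=2, p=probs))
            rows.append((sample_id, gene, a1, a2, "hom" if a1 == a2 else "het"))
    return pd.DataFrame(rows, columns=["sample_id", "gene", "allele1", "allele2", "zygosity"])


def simulate_hla_reads(truth: pd.DataFrame, spec: CohortSpec) -> list[GeneReadCounts]:
    """Noisy allele read-count profiles for every (sample, gene) of the truth.

    Depth is gamma-Poisson (negative binomial) around ``depth_mean``;
    reads split evenly in expectation between the two true alleles, and
    each read leaks to a uniformly random other allele of the gene with
    probability ``cross_mapping_rate``.
    """
    rng = _substream(spec.seed, "reads")
    out: list[GeneReadCounts] = []
    for rec in truth.itertuples(index=False):
        pool = sorted(spec.allele_pools[rec.gene])
        k = spec.depth_dispersion
        depth = int(rng.negative_binomial(k, k / (k + spec.depth_mean))) if spec.depth_mean > 0 else 0
        counts: dict[str, float] = {}
        if rec.allele1 == rec.allele2:
            allocations = [(rec.allele1, depth)]
        else:
            n1 = int(rng.binomial(depth, 0.5))
            allocations = [(rec.allele1, n1), (rec.allele2, depth - n1)]
        for allele, n in allocations:
            n_leak = int(rng.binomial(n, spec.cross_mapping_rate)) if n else 0
            counts[allele] = counts.get(allele, 0.0) + (n - n_leak)
            others = [a for a in pool if a != allele]
            if n_leak and others:
                for a, m in zip(others, rng.multinomial(n_leak, [1 / len(others)] * len(others))):
                    if m:
                        counts[a] = counts.get(a, 0.0) + m
        out.append(GeneReadCounts(rec.sample_id, rec.gene, {a: c for a, c in sorted(counts.items()) if c > 0}))
    return out


def _peptide(index: int, length: int = 9) -> str:
    """Deterministic distinct 9-mer for a global peptide index."""
    chars = []
    for _ in range(length):
        index, r = divmod(index, len(AMINO_ACIDS))
        chars.append(AMINO_ACIDS[r])
    return "".join(chars)


def simulate_presentation(spec: CohortSpec, peptidome_size: int = 2400) -> PresentationMap:
    """Construct per-allele presented sets realizing the overlap kernel.

    Each class I allele gets ``peptidome_size // n_alleles`` synthetic
    9-mers.  A hierarchical kernel is realized exactly via nested cores:
    a gene-wide core shared by all alleles of the gene, a family core on
    top of it, and private peptides.  An explicit pairwise kernel is
    realized with one dedicated shared block per pair; it is infeasible
    (raises ValueError) when an allele's requested overlaps exceed its
    set size.
    """
    alleles_by_gene = {g: sorted(spec.allele_pools[g]) for g in CLASS_I_GENES}
    n_alleles = sum(len(v) for v in alleles_by_gene.values())
    m = max(10, peptidome_size // n_alleles)
    counter = itertools.count()

    def block(size: int) -> set[str]:
        return {_peptide(next(counter)) for _ in range(size)}

    def overlap(j: float) -> int:
        # |A|=|B|=m and J = O/(2m-O)  =>  O = 2mJ/(1+J)
        return round(2 * m * j / (1 + j))

    sets: dict[str, set[str]] = {}
    kernel = spec.peptide_overlap_kernel
    if isinstance(kernel, HierarchicalKernel):
        if not 0 <= kernel.between <= kernel.within <= 1:
            raise ValueError("hierarchical kernel needs 0 <= between <= within <= 1")
        o_w, o_c = overlap(kernel.within), overlap(kernel.between)
        for gene, alleles in alleles_by_gene.items():
            fam = HierarchicalKernel.family_of(kernel, alleles)
            gene_core = block(o_c)
            family_cores = {f: block(o_w - o_c) for f in set(fam.values())}
            for a in alleles:
                sets[a] = gene_core | family_cores[fam[a]] | block(m - o_w)
    else:
        _pairwise_sets(kernel, alleles_by_gene, m, block, overlap, sets)
    return PresentationMap(sets=sets)


def _pairwise_sets(kernel, alleles_by_gene, m, block, overlap, sets) -> None:
    """Dedicated-block realization of an explicit pairwise Jaccard kernel."""
    targets: dict[tuple[str, str], float] = {}
    for (a, b), j in kernel.items():
        if not 0 <= j <= 1:
            raise ValueError(f"kernel value {j} for pair ({a},{b}) outside [0,1]")
        targets[tuple(sorted((a, b)))] = j
    # alleles requested at J=1 share one identical set (merge groups)
    parent: dict[str, str] = {}

    def find(a: str) -> str:
        parent.setdefault(a, a)
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for (a, b), j in targets.items():
        if j == 1.0:
            parent[find(a)] = find(b)
    shared: dict[str, set[str]] = {}
    for gene, alleles in alleles_by_gene.items():
        budgets = {a: m for a in alleles}
        blocks: dict[str, set[str]] = {a: set() for a in alleles}
        reps = {a: find(a) for a in alleles}
        pair_targets = [
            (pair, j)
            for pair, j in targets.items()
            if pair[0] in reps and pair[1] in reps and j < 1.0 and reps[pair[0]] != reps[pair[1]]
        ]
        for (a, b), j in sorted(pair_targets):
            o = overlap(j)
            ra, rb = reps[a], reps[b]
            if budgets[ra] < o or budgets[rb] < o:
                raise ValueError(f"infeasible kernel: overlaps of allele {a} or {b} exceed set size {m}")
            blk = block(o)
            blocks[ra] |= blk
            blocks[rb] |= blk
            budgets[ra] -= o
            budgets[rb] -= o
        for a in alleles:
            r = reps[a]
            if r not in shared:
                shared[r] = blocks[r] | block(budgets[r])
            sets[a] = shared[r]


def suppression_targets(peptides: set[str], n_otus: int) -> set[int]:
    """OTU indices suppressed by a presented-peptide set (stable hashing)."""
    return {_stable_hash(p) % n_otus for p in peptides}


def simulate_microbiota(truth: pd.DataFrame, pmap: PresentationMap, spec: CohortSpec) -> OtuTable:
    """OTU table with a PPSS-coupled planted effect.

    A shared log-normal baseline sets each OTU's typical abundance; each
    class I allele of an individual suppresses the OTUs its presented
    peptides hash to, multiplying them by ``exp(-effect_size)`` per
    suppressing allele slot; log-normal noise of scale ``noise_sd`` is
    added and rows are scaled to ``sample_depth`` reads.  Individuals
    with overlapping presented peptidomes therefore share suppression
    patterns, making their communities more similar; with
    ``effect_size=0`` the communities are exchangeable.
    """
    base_rng = _substream(spec.seed, "baseline")
    baseline = np.exp(base_rng.normal(0.0, spec.baseline_sigma, size=spec.n_otus))
    noise_rng = _substream(spec.seed, "microbiota")
    targets = {a: sorted(suppression_targets(s, spec.n_otus)) for a, s in pmap.sets.items()}
    samples = sorted(truth["sample_id"].unique())
    class1 = truth[truth["gene"].isin(CLASS_I_GENES)]
    rows = np.zeros((len(samples), spec.n_otus))
    for i, sample_id in enumerate(samples):
        hits = np.zeros(spec.n_otus)
        sub = class1[class1["sample_id"] == sample_id]
        for rec in sub.itertuples(index=False):
            for allele in (rec.allele1, rec.allele2):
                if allele in targets:
                    hits[targets[allele]] += 1.0
        noise = np.exp(noise_rng.normal(0.0, spec.noise_sd, size=spec.n_otus)) if spec.noise_sd > 0 else 1.0
        abund = baseline * np.exp(-spec.effect_size * hits) * noise
        rows[i] = abund / abund.sum() * spec.sample_depth
    otu_ids = [f"OTU{i:04d}" for i in range(spec.n_otus)]
    mat = pd.DataFrame(rows, index=samples, columns=otu_ids)
    return OtuTable(mat, synthetic_lineages(spec.n_otus), mat.sum(axis=1))


def synthetic_lineages(n_otus: int) -> dict[str, list[str]]:
    """Balanced six-rank taxonomy (domain→genus) for synthetic OTUs."""
    out = {}
    for i in range(n_otus):
        out[f"OTU{i:04d}"] = [
            "Bacteria",
            f"Phylum{i // 30}",
            f"Class{i // 15}",
            f"Order{i // 6}",
            f"Family{i // 3}",
            f"Genus{i}",
        ]
    return out


def simulate_proteins(
    n: int,
    length_dist: int | tuple[int, int] = (80, 300),
    seed: int | np.random.Generator = 0,
) -> list[tuple[str, str]]:
    """Random protein sequences (i.i.d. canonical residues) as (id, seq) pairs."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    aas = np.array(list(AMINO_ACIDS))
    out = []
    for i in range(n):
        length = length_dist if isinstance(length_dist, int) else int(rng.integers(length_dist[0], length_dist[1] + 1))
        if length < 9:
            raise ValueError("protein length must be >= 9")
        out.append((f"prot{i:05d}", "".join(rng.choice(aas, size=length))))
    return out


class HashRankPredictor:
    """Deterministic synthetic binding predictor for tests and simulations.

    Assigns each (allele, peptide) pair a pseudo-uniform percentile rank
    in (0, 100] from a stable hash, so roughly ``rank_cutoff`` percent of
    any peptidome is presented by each allele.
    """

    def __call__(self, allele: str, peptide: str) -> float:
        h = _stable_hash(f"{allele}|{peptide}")
        return (h % 100_000) / 1000.0 + 0.001


@dataclass
class SimulatedCohort:
    """Everything a pipeline run needs, with ground truth attached."""

    spec: CohortSpec
    truth: pd.DataFrame
    gene_counts: list[GeneReadCounts]
    pmap: PresentationMap
    otu_table: OtuTable


def simulate_cohort(spec: CohortSpec, peptidome_size: int = 2400) -> SimulatedCohort:
    """Run all generator stages off one seed and bundle the results."""
    truth = simulate_haplotypes(spec)
    counts = simulate_hla_reads(truth, spec)
    pmap = simulate_presentation(spec, peptidome_size)
    table = simulate_microbiota(truth, pmap, spec)
    return SimulatedCohort(spec, truth, counts, pmap, table)
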