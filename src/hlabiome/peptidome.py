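"""Presented peptidomes and the presented peptidome similarity score (PPSS).

A peptidome is a set of 9-mer peptides sampled by sliding a window over
protein sequences and keeping each candidate independently with a small
probability.  A binding predictor (any callable scoring (allele, peptide)
with a percentile rank, lower = stronger) turns the peptidome into one
presented-peptide set per HLA class I allele, using the conventional
2.0 %Rank cutoff.  The functional similarity of two alleles is the
Jaccard index of their presented sets

    J_ab = |P_a ∩ P_b| / (|P_a| + |P_b| − |P_a ∩ P_b|)

and the PPSS of two class-I-complete individuals is the sum of J over
all 2x2 allele combinations of each of the three class I genes
(HLA-A, -B, -C), so it ranges from 0 (no overlap anywhere) to 12
(identical presented peptides throughout).  Homozygous genes enter the
2x2 sum with their single allele duplicated.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Protocol

import numpy as np
import pandas as pd

from .config import CLASS_I_GENES, CLASS_II_GENES, logger
from .hla_typing import HlaProfile

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)


class BindingPredictor(Protocol):
    """Percentile-rank binding predictor: lower rank = stronger binder.

    Must be deterministic for a fixed (allele, peptide) pair.
    """

    def __call__(self, allele: str, peptide: str) -> float: ...


def sample_peptidome(
    proteins: Iterable[tuple[str, str]] | Iterable[str],
    window: int = 9,
    rate: float = 0.001,
    seed: int | np.random.Generator = 0,
) -> set[str]:
    """Sample a peptidome from protein sequences by sliding-window Bernoulli draws.

    Every length-``window`` substring of every protein is a candidate
    (a protein of length L yields L − window + 1 candidates; shorter
    proteins are skipped); each candidate is kept independently with
    probability ``rate`` and duplicates are removed afterwards.  Windows
    containing non-canonical residues are skipped with a warning.
    Reproducible for a fixed seed.
    """
    if not 0 < rate <= 1:
        raise ValueError("rate must be in (0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: set[str] = set()
    n_skipped = 0
    for rec in proteins:
        seq = (rec[1] if isinstance(rec, tuple) else rec).upper()
        for i in range(len(seq) - window + 1):
            pep = seq[i : i + window]
            if not _AA_SET.issuperset(pep):
                n_skipped += 1
                continue
            if rate >= 1.0 or rng.random() < rate:
                out.add(pep)
    if n_skipped:
        logger.warning("sample_peptidome: skipped %d windows with non-canonical residues", n_skipped)
    return out


def presented_set(
    allele: str,
    peptidome: Iterable[str],
    predictor: BindingPredictor,
    rank_cutoff: float = 2.0,
) -> set[str]:
    """Peptides of the peptidome presented by an allele (%Rank ≤ cutoff)."""
    try:
        return {p for p in peptidome if predictor(allele, p) <= rank_cutoff}
    except Exception as exc:  # predictor failure surfaces as a missing allele
        raise KeyError(f"binding prediction failed for allele {allele}") from exc


def jaccard(set_a: set[str], set_b: set[str]) -> float:
    """Jaccard index of two peptide sets; two empty sets score 0 by convention."""
    if not set_a and not set_b:
        return 0.0
    o = len(set_a & set_b)
    return o / (len(set_a) + len(set_b) - o)


@dataclass
class PresentationMap:
    """Allele → presented-peptide set, or a precomputed allele-pair Jaccard table.

    Either ``sets`` or ``jaccard_table`` (or both) may be populated; pair
    similarities are looked up from the table when available and computed
    from the sets otherwise.
    """

    sets: dict[str, set[str]] = field(default_factory=dict)
    jaccard_table: dict[tuple[str, str], float] = field(default_factory=dict)

    @classmethod
    def from_predictor(
        cls,
        alleles: Iterable[str],
        peptidome: Iterable[str],
        predictor: BindingPredictor,
        rank_cutoff: float = 2.0,
    ) -> "PresentationMap":
        peps = set(peptidome)
        return cls(sets={a: presented_set(a, peps, predictor, rank_cutoff) for a in alleles})

    def alleles(self) -> set[str]:
        return set(self.sets) | {a for pair in self.jaccard_table for a in pair}

    def pair_jaccard(self, allele_a: str, allele_b: str) -> float:
        """J for an allele pair, preferring the precomputed table."""
        if self.jaccard_table:
            key = (allele_a, allele_b) if (allele_a, allele_b) in self.jaccard_table else (allele_b, allele_a)
            if key in self.jaccard_table:
                return self.jaccard_table[key]
            if allele_a == allele_b and allele_a in {x for k in self.jaccard_table for x in k}:
                return 1.0  # diagonal of a table that only stores off-diagonal pairs
        for a in (allele_a, allele_b):
            if a not in self.sets:
                raise KeyError(f"allele {a} missing from presentation map")
        return jaccard(self.sets[allele_a], self.sets[allele_b])

    def to_table(self) -> "PresentationMap":
        """Materialize the dense symmetric J table from the peptide sets."""
        table: dict[tuple[str, str], float] = {}
        for a, b in itertools.combinations_with_replacement(sorted(self.sets), 2):
            table[(a, b)] = jaccard(self.sets[a], self.sets[b])
        return PresentationMap(jaccard_table=table)


def _class1_genotypes(profile: HlaProfile) -> dict[str, tuple[str, str]]:
    if not profile.class1_complete:
        raise ValueError(f"profile {profile.sample_id} is not class I complete")
    return {g: profile.calls[g].alleles for g in CLASS_I_GENES}


def ppss(profile_i: HlaProfile, profile_j: HlaProfile, pmap: PresentationMap) -> float:
    """PPSS of two class-I-complete profiles: Σ_g Σ_{ai} Σ_{aj} J_{g,ai,aj}.

    The inner sums run over both allele slots of each individual, so a
    homozygous gene contributes its single allele twice and the score is
    bounded by 12 (3 genes × 4 combinations × J ≤ 1).
    """
    gi, gj = _class1_genotypes(profile_i), _class1_genotypes(profile_j)
    total = 0.0
    for g in CLASS_I_GENES:
        for ai in gi[g]:
            for aj in gj[g]:
                total += pmap.pair_jaccard(ai, aj)
    return total


def ppss_matrix(profiles: list[HlaProfile], pmap: PresentationMap) -> pd.DataFrame:
    """PPSS for all unordered pairs of class-I-complete profiles.

    Returns a long-format frame with columns ``sample_i``, ``sample_j``
    and ``ppss`` (n(n−1)/2 rows); symmetric by construction.
    """
    rows = [
        (p.sample_id, q.sample_id, ppss(p, q, pmap))
        for p, q in itertools.combinations(profiles, 2)
    ]
    return pd.DataFrame(rows, columns=["sample_i", "sample_j", "ppss"])


def shared_alleles(profile_i: HlaProfile, profile_j: HlaProfile, hla_class: int = 1) -> int:
    """Number of shared alleles between two profiles of one HLA class (0–6).

    Per gene, the size of the multiset intersection of the two 2-allele
    genotypes (a homozygote contributes its allele twice), summed over
    the class's three genes.
    """
    genes = CLASS_I_GENES if hla_class == 1 else CLASS_II_GENES
    for p in (profile_i, profile_j):
        if not p.is_complete(hla_class):
            raise ValueError(f"profile {p.sample_id} is not class {hla_class} complete")
    n = 0
    for g in genes:
        n += sum((Counter(profile_i.calls[g].alleles) & Counter(profile_j.calls[g].alleles)).values())
    return n


def supertype_similarity(
    profile_i: HlaProfile,
    profile_j: HlaProfile,
    supertype_map: dict[str, str],
) -> int:
    """Shared supertypes across the HLA-A and HLA-B genotypes (0–4).

    Alleles are translated to supertypes and compared per gene as a
    multiset intersection, like :func:`shared_alleles`.  Alleles absent
    from the map are excluded (and counted in a warning).
    """
    n = 0
    n_unmapped = 0
    for g in ("A", "B"):
        multisets = []
        for p in (profile_i, profile_j):
            sts = [supertype_map[a] for a in p.calls[g].alleles if a in supertype_map]
            n_unmapped += len(p.calls[g].alleles) - len(sts)
            multisets.append(Counter(sts))
        n += sum((multisets[0] & multisets[1]).values())
    if n_unmapped:
        logger.warning("supertype_similarity: %d alleles without a supertype", n_unmapped)
    return n
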