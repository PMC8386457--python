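"""Peptidome sampling, presented sets, Jaccard and PPSS."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hlabiome.peptidome import (
    PresentationMap,
    jaccard,
    ppss,
    ppss_matrix,
    presented_set,
    sample_peptidome,
    shared_alleles,
    supertype_similarity,
)
from hlabiome.simulate import HashRankPredictor, _peptide

from conftest import make_profile

GENES = ("A", "B", "C")


def class1_profile(sample_id, genotypes):
    return make_profile(sample_id, dict(zip(GENES, genotypes)))


def peptides(n, offset=0):
    return {_peptide(offset + i) for i in range(n)}


class TestSamplePeptidome:
    def test_rate_one_enumerates_every_window(self):
        """Oracle: at rate 1 the peptidome is the deduped set of all 9-mers."""
        rng = np.random.default_rng(1)
        seqs = ["".join(rng.choice(list("ACDEFGHIKL"), size=30)) for _ in range(5)]
        expected = {s[i : i + 9] for s in seqs for i in range(len(s) - 8)}
        assert sample_peptidome(seqs, rate=1.0, seed=0) == expected

    def test_single_window_protein(self):
        assert sample_peptidome(["ACDEFGHIK"], rate=1.0, seed=0) == {"ACDEFGHIK"}

    def test_window_count_is_length_minus_eight(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"  # length 20, all distinct windows
        assert len(sample_peptidome([seq], rate=1.0, seed=0)) == 12

    def test_short_proteins_and_bad_residues_are_skipped(self):
        assert sample_peptidome(["ACDEFGHI", "ACDEFGHIX"], rate=1.0, seed=0) == set()

    def test_same_seed_reproduces_the_sample(self):
        rng = np.random.default_rng(2)
        seqs = ["".join(rng.choice(list("ACDEFGHIKL"), size=200)) for _ in range(10)]
        a = sample_peptidome(seqs, rate=0.05, seed=42)
        assert a == sample_peptidome(seqs, rate=0.05, seed=42)
        assert 0 < len(a) < 200 * 10

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            sample_peptidome(["ACDEFGHIK"], rate=0.0)


class TestPresentedSet:
    peptidome = peptides(40)

    def test_nothing_passes_a_constant_high_rank(self):
        assert presented_set("A*01", self.peptidome, lambda a, p: 50.0) == set()

    def test_cutoff_is_inclusive(self):
        assert presented_set("A*01", self.peptidome, lambda a, p: 2.0) == self.peptidome

    def test_motif_predictor_selects_exactly_the_motif(self):
        motif = lambda a, p: 1.0 if p.startswith("K") else 50.0
        expected = {p for p in self.peptidome if p.startswith("K")}
        assert presented_set("A*01", self.peptidome, motif) == expected

    def test_predictor_failure_names_the_allele(self):
        def broken(allele, pep):
            raise RuntimeError("model not loaded")

        with pytest.raises(KeyError, match="B[*]99"):
            presented_set("B*99", self.peptidome, broken)

    def test_hash_predictor_presents_about_the_cutoff_fraction(self):
        pool = peptides(4000)
        pres = presented_set("A*01", pool, HashRankPredictor(), rank_cutoff=2.0)
        assert 0.01 < len(pres) / len(pool) < 0.03


class TestJaccard:
    def test_identical_nonempty_sets(self):
        assert jaccard({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint_sets(self):
        assert jaccard({"a"}, {"b"}) == 0.0

    def test_partial_overlap(self):
        assert jaccard({"a", "b", "c"}, {"b", "c", "d"}) == pytest.approx(0.5)

    def test_both_empty_is_zero_by_convention(self):
        assert jaccard(set(), set()) == 0.0

    @given(
        st.sets(st.integers(0, 20)),
        st.sets(st.integers(0, 20)),
        st.sets(st.integers(21, 30)),
    )
    def test_symmetric_and_monotone_under_shared_growth(self, a, b, extra):
        assert jaccard(a, b) == jaccard(b, a)
        assert 0 <= jaccard(a, b) <= 1
        # adding the same new elements to both sets cannot reduce overlap
        assert jaccard(a | extra, b | extra) >= jaccard(a, b)


class TestPpss:
    def identical_map(self):
        shared = peptides(20)
        alleles = [f"{g}*{i:02d}" for g in GENES for i in (1, 2)]
        return PresentationMap(sets={a: set(shared) for a in alleles})

    def disjoint_map(self):
        alleles = [f"{g}*{i:02d}" for g in GENES for i in (1, 2, 3, 4)]
        return PresentationMap(sets={a: peptides(10, offset=100 * k) for k, a in enumerate(alleles)})

    def two_profiles(self):
        p1 = class1_profile("s1", [("A*01", "A*02"), ("B*01", "B*02"), ("C*01", "C*02")])
        p2 = class1_profile("s2", [("A*01", "A*02"), ("B*01", "B*02"), ("C*01", "C*02")])
        return p1, p2

    def test_identical_presented_sets_reach_the_maximum_of_12(self):
        p1, p2 = self.two_profiles()
        assert ppss(p1, p2, self.identical_map()) == pytest.approx(12.0)

    def test_disjoint_presented_sets_score_0(self):
        p1 = class1_profile("s1", [("A*01", "A*02"), ("B*01", "B*02"), ("C*01", "C*02")])
        p2 = class1_profile("s2", [("A*03", "A*04"), ("B*03", "B*04"), ("C*03", "C*04")])
        assert ppss(p1, p2, self.disjoint_map()) == 0.0

    def test_homozygous_identical_gene_contributes_4(self):
        shared = peptides(15)
        pmap = PresentationMap(
            sets={
                "A*01": set(shared),
                "B*01": peptides(10, 100),
                "B*02": peptides(10, 200),
                "C*01": peptides(10, 300),
                "C*02": peptides(10, 400),
            }
        )
        p1 = class1_profile("s1", [("A*01", "A*01"), ("B*01", "B*01"), ("C*01", "C*01")])
        p2 = class1_profile("s2", [("A*01", "A*01"), ("B*02", "B*02"), ("C*02", "C*02")])
        assert ppss(p1, p2, pmap) == pytest.approx(4.0)

    def test_missing_allele_is_named_in_the_error(self):
        p1, p2 = self.two_profiles()
        pmap = self.identical_map()
        del pmap.sets["C*02"]
        with pytest.raises(KeyError, match="C[*]02"):
            ppss(p1, p2, pmap)

    def test_incomplete_profile_rejected(self):
        p1, _ = self.two_profiles()
        partial = make_profile("s3", {"A": ("A*01", "A*02")})
        with pytest.raises(ValueError):
            ppss(p1, partial, self.identical_map())

    def test_self_ppss_closed_form(self):
        """ppss(i,i) = 2·Σ_g (1 + J(a1,a2)); 12 only for within-gene identity."""
        rng = np.random.default_rng(0)
        pool = sorted(peptides(300))
        sets = {
            f"{g}*{i:02d}": set(rng.choice(pool, size=40, replace=False))
            for g in GENES
            for i in (1, 2)
        }
        pmap = PresentationMap(sets=sets)
        p = class1_profile("s1", [("A*01", "A*02"), ("B*01", "B*02"), ("C*01", "C*02")])
        expected = 2 * sum(
            1 + jaccard(sets[f"{g}*01"], sets[f"{g}*02"]) for g in GENES
        )
        assert ppss(p, p, pmap) == pytest.approx(expected)
        assert ppss(p, p, pmap) < 12.0

    def test_sets_and_precomputed_table_agree(self):
        """Oracle equivalence of the two PPSS routes on random sets."""
        rng = np.random.default_rng(7)
        pool = sorted(peptides(500))
        profiles = []
        sets = {}
        for k in range(10):
            genotypes = []
            for g in GENES:
                a1, a2 = f"{g}*{rng.integers(1, 5):02d}", f"{g}*{rng.integers(1, 5):02d}"
                genotypes.append(tuple(sorted((a1, a2))))
            profiles.append(class1_profile(f"s{k}", genotypes))
        for g in GENES:
            for i in range(1, 5):
                sets[f"{g}*{i:02d}"] = set(rng.choice(pool, size=60, replace=False))
        pmap_sets = PresentationMap(sets=sets)
        pmap_table = pmap_sets.to_table()
        for p, q in itertools.combinations(profiles, 2):
            assert abs(ppss(p, q, pmap_sets) - ppss(p, q, pmap_table)) < 1e-12


class TestPpssMatrix:
    def test_all_unordered_pairs_scored(self):
        profiles = [
            class1_profile(f"s{i}", [("A*01", "A*02"), ("B*01", "B*02"), ("C*01", "C*02")])
            for i in range(5)
        ]
        shared = peptides(10)
        pmap = PresentationMap(sets={a: set(shared) for a in ("A*01", "A*02", "B*01", "B*02", "C*01", "C*02")})
        mat = ppss_matrix(profiles, pmap)
        assert len(mat) == 10
        assert (mat["ppss"] == 12.0).all()

    def test_single_profile_gives_empty_matrix(self):
        p = class1_profile("s1", [("A*01", "A*01"), ("B*01", "B*01"), ("C*01", "C*01")])
        pmap = PresentationMap(sets={a: peptides(5) for a in ("A*01", "B*01", "C*01")})
        assert len(ppss_matrix([p], pmap)) == 0

    def test_duplicate_profile_pair_attains_the_maximum(self):
        rng = np.random.default_rng(3)
        pool = sorted(peptides(400))
        sets = {
            f"{g}*{i:02d}": set(rng.choice(pool, size=50, replace=False))
            for g in GENES
            for i in (1, 4)
        }
        pmap = PresentationMap(sets=sets)
        twin = [("A*01", "A*04"), ("B*01", "B*04"), ("C*01", "C*04")]
        profiles = [
            class1_profile("t1", twin),
            class1_profile("t2", twin),
            class1_profile("s3", [("A*01", "A*01"), ("B*04", "B*04"), ("C*01", "C*04")]),
        ]
        mat = ppss_matrix(profiles, pmap)
        twin_score = mat.query("sample_i=='t1' and sample_j=='t2'")["ppss"].iloc[0]
        assert twin_score >= mat["ppss"].max() - 1e-9


class TestSharedAlleles:
    def test_identical_heterozygous_profiles_share_six(self):
        p = class1_profile("s1", [("A*01", "A*02"), ("B*01", "B*02"), ("C*01", "C*02")])
        q = class1_profile("s2", [("A*01", "A*02"), ("B*01", "B*02"), ("C*01", "C*02")])
        assert shared_alleles(p, q) == 6

    def test_fully_distinct_profiles_share_none(self):
        p = class1_profile("s1", [("A*01", "A*02"), ("B*01", "B*02"), ("C*01", "C*02")])
        q = class1_profile("s2", [("A*03", "A*04"), ("B*03", "B*04"), ("C*03", "C*04")])
        assert shared_alleles(p, q) == 0

    def test_homozygote_intersects_heterozygote_once(self):
        p = class1_profile("s1", [("A*01", "A*01"), ("B*01", "B*02"), ("C*01", "C*02")])
        q = class1_profile("s2", [("A*01", "A*02"), ("B*03", "B*04"), ("C*03", "C*04")])
        assert shared_alleles(p, q) == 1

    def test_incomplete_profile_rejected(self):
        p = class1_profile("s1", [("A*01", "A*01"), ("B*01", "B*02"), ("C*01", "C*02")])
        q = make_profile("s2", {"A": ("A*01", "A*02")})
        with pytest.raises(ValueError):
            shared_alleles(p, q)


class TestSupertypeSimilarity:
    smap = {"A*01": "A01", "A*02": "A02", "A*03": "A03", "B*01": "B07", "B*02": "B44"}

    def test_identical_mapped_profiles_share_four(self):
        p = class1_profile("s1", [("A*01", "A*02"), ("B*01", "B*02"), ("C*01", "C*02")])
        q = class1_profile("s2", [("A*01", "A*02"), ("B*01", "B*02"), ("C*01", "C*02")])
        assert supertype_similarity(p, q, self.smap) == 4

    def test_disjoint_supertypes_share_none(self):
        p = class1_profile("s1", [("A*01", "A*01"), ("B*01", "B*01"), ("C*01", "C*01")])
        q = class1_profile("s2", [("A*02", "A*03"), ("B*02", "B*02"), ("C*02", "C*02")])
        assert supertype_similarity(p, q, self.smap) == 0

    def test_one_shared_a_supertype(self):
        p = class1_profile("s1", [("A*01", "A*02"), ("B*01", "B*01"), ("C*01", "C*01")])
        q = class1_profile("s2", [("A*01", "A*03"), ("B*02", "B*02"), ("C*02", "C*02")])
        assert supertype_similarity(p, q, self.smap) == 1

    def test_unmapped_alleles_are_excluded(self):
        p = class1_profile("s1", [("A*09", "A*09"), ("B*01", "B*01"), ("C*01", "C*01")])
        q = class1_profile("s2", [("A*09", "A*09"), ("B*01", "B*01"), ("C*01", "C*01")])
        # A*09 has no supertype: only the shared B supertypes count
        assert supertype_similarity(p, q, self.smap) == 2
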