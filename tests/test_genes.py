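"""SNP-to-gene mapping, NS/synonymous triage against a full-translation
oracle, candidate-set construction and overlap bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

import convergescan as cs
from convergescan.genes import DataError, GeneModel, OUTLIER_ANALYSIS


def simple_model(strand="+", species="A"):
    # single-exon 9 nt CDS: ATG GCT TAA on the coding strand
    seq = "ATGGCTTAA"
    genomic = seq if strand == "+" else str(Seq(seq).reverse_complement())
    return GeneModel(
        species=species, gene_id="g1", chrom="c1", start=1, end=20,
        strand=strand, cds_segments=((5, 13),),
        cds_sequence=seq,
    ), genomic


class TestClassifyEffect:
    def test_third_position_fourfold_is_synonymous(self):
        model, _ = simple_model("+")
        # codon 2 is GCT (Ala); third base at genomic pos 5+5=10, T->A -> GCA
        assert cs.classify_effect(model, 10, "T", "A") == "synonymous"

    def test_second_position_is_nonsynonymous(self):
        model, _ = simple_model("+")
        # GCT -> GTT : Ala -> Val
        assert cs.classify_effect(model, 9, "C", "T") == "nonsynonymous"

    def test_minus_strand_uses_complemented_alleles(self):
        model, _ = simple_model("-")
        # coding GCT third base maps to genomic pos 5 + (9-1-5) = 8 with
        # complemented alleles: coding T->A is genomic A->T
        assert cs.classify_effect(model, 8, "A", "T") == "synonymous"
        # coding second base C->T is genomic G->A at pos 9
        assert cs.classify_effect(model, 9, "G", "A") == "nonsynonymous"

    def test_intron_between_segments_is_noncoding(self):
        model = GeneModel(
            species="A", gene_id="g2", chrom="c1", start=1, end=40, strand="+",
            cds_segments=((5, 10), (21, 23)), cds_sequence="ATGGCTTAA",
        )
        assert cs.classify_effect(model, 15, "A", "T") == "noncoding"

    def test_ref_mismatch_is_data_error(self):
        model, _ = simple_model("+")
        with pytest.raises(DataError, match="does not match"):
            cs.classify_effect(model, 10, "G", "A")

    def test_agrees_with_full_translation_oracle(self):
        """Translate the whole CDS before/after the substitution and compare."""
        rng = np.random.default_rng(9)
        bases = np.array(list("ACGT"))
        for _ in range(300):
            n_codons = int(rng.integers(2, 8))
            seq = "".join(rng.choice(bases, 3 * n_codons))
            strand = rng.choice(["+", "-"])
            l1 = int(rng.integers(1, 3 * n_codons))
            start = 11
            seg1 = (start, start + l1 - 1)
            gap = int(rng.integers(1, 20))
            seg2 = (seg1[1] + gap + 1, seg1[1] + gap + (3 * n_codons - l1))
            model = GeneModel(
                species="A", gene_id="g", chrom="c", start=1, end=seg2[1] + 5,
                strand=strand, cds_segments=(seg1, seg2), cds_sequence=seq,
            )
            ci = int(rng.integers(0, 3 * n_codons))
            ref_coding = seq[ci]
            alt_coding = str(rng.choice(bases[bases != ref_coding]))
            # genomic position and alleles for this coding-strand site
            gen_off = ci if strand == "+" else 3 * n_codons - 1 - ci
            pos = seg1[0] + gen_off if gen_off < l1 else seg2[0] + gen_off - l1
            comp = str.maketrans("ACGT", "TGCA")
            ref = ref_coding if strand == "+" else ref_coding.translate(comp)
            alt = alt_coding if strand == "+" else alt_coding.translate(comp)
            got = cs.classify_effect(model, pos, ref, alt)
            mutated = seq[:ci] + alt_coding + seq[ci + 1:]
            oracle = (
                "synonymous"
                if Seq(seq).translate() == Seq(mutated).translate()
                else "nonsynonymous"
            )
            assert got == oracle, (seq, strand, ci, ref, alt)


class TestMapSnps:
    @pytest.fixture()
    def models(self):
        mk = lambda gid, start, end: GeneModel(
            species="A", gene_id=gid, chrom="c1", start=start, end=end,
            strand="+", cds_segments=(), cds_sequence="",
        )
        return [mk("g1", 100, 200), mk("g2", 150, 250)]

    def test_boundaries_inclusive(self, models):
        snps = pd.DataFrame({"chrom": ["c1", "c1", "c1"], "pos": [100, 200, 99]})
        out = cs.map_snps_to_genes(snps, models)
        assert list(out.loc[out["pos"] == 100, "gene"]) == ["g1"]
        assert out.loc[out["pos"] == 99, "gene"].isna().all()

    def test_overlapping_genes_get_both_assignments(self, models):
        snps = pd.DataFrame({"chrom": ["c1"], "pos": [175]})
        out = cs.map_snps_to_genes(snps, models)
        assert sorted(out["gene"]) == ["g1", "g2"]

    def test_other_chromosome_unassigned(self, models):
        out = cs.map_snps_to_genes(pd.DataFrame({"chrom": ["c2"], "pos": [150]}), models)
        assert out["gene"].isna().all()

    def test_roundtrip_against_generator_assignments(self, small_universe, small_config, small_tables):
        t = small_tables["C"]
        models = cs.gen_gene_models(small_universe, small_config, "C")
        remapped = cs.map_snps_to_genes(t.drop(columns="gene"), models)
        assert len(remapped) == len(t)
        assert (remapped["gene"].to_numpy() == t["gene"].to_numpy()).all()


def _flags(species, rows):
    """rows: (gene, effect, outlier, sigF1)"""
    return pd.DataFrame(
        [{"gene": g, "effect": e, "outlier": o, "sig_F1": s} for g, e, o, s in rows]
    )


@pytest.fixture()
def tiny_universe():
    return cs.OrthologUniverse(
        species_ids=("s1", "s2", "s3"),
        annotated={
            "s1": frozenset("abcx"), "s2": frozenset("abcy"), "s3": frozenset("abcz"),
        },
    )


class TestCandidateSets:
    def test_flagged_snp_makes_gene_candidate(self, tiny_universe):
        flagged = {
            "s1": _flags("s1", [("a", "synonymous", False, True)]),
            "s2": _flags("s2", [("a", "noncoding", True, False)]),
            "s3": _flags("s3", [("a", "nonsynonymous", False, False)]),
        }
        coll = cs.build_candidate_sets(flagged, tiny_universe, ["F1"])
        assert coll.sets[("F1", "s1")] == {"a"}
        assert coll.sets[(OUTLIER_ANALYSIS, "s2")] == {"a"}
        assert coll.sets[("F1", "s3")] == frozenset()

    def test_unannotated_gene_excluded_and_counted(self, tiny_universe):
        flagged = {
            "s1": _flags("s1", [("nope", "noncoding", True, False)]),
            "s2": _flags("s2", []),
            "s3": _flags("s3", []),
        }
        flagged["s2"] = _flags("s2", [])
        flagged["s2"] = pd.DataFrame(columns=["gene", "effect", "outlier", "sig_F1"])
        flagged["s3"] = pd.DataFrame(columns=["gene", "effect", "outlier", "sig_F1"])
        coll = cs.build_candidate_sets(flagged, tiny_universe, ["F1"])
        assert coll.sets[(OUTLIER_ANALYSIS, "s1")] == frozenset()
        assert coll.n_unannotated["s1"] == 1

    def test_unflagged_snps_never_create_candidates(self, tiny_universe):
        flagged = {
            s: _flags(s, [("a", "nonsynonymous", False, False)] * 10)
            for s in tiny_universe.species_ids
        }
        coll = cs.build_candidate_sets(flagged, tiny_universe, ["F1"])
        assert all(not coll.sets[k] for k in coll.sets)


class TestOverlapTable:
    def _collection(self, sets_by_species, ns=None):
        sp = tuple(sets_by_species)
        return cs.CandidateSetCollection(
            species_ids=sp,
            analyses=("outlier",),
            sets={("outlier", s): frozenset(v) for s, v in sets_by_species.items()},
            flagged_ns={("outlier", s): frozenset() for s in sp},
            ns_genes={s: frozenset((ns or {}).get(s, ())) for s in sp},
        )

    def test_enumerated_pairwise_and_threeway(self):
        coll = self._collection({"s1": "abc", "s2": "bcd", "s3": "ce"})
        row = cs.overlap_table(coll).iloc[0]
        assert (row["s1"], row["s2"], row["s3"]) == (3, 3, 2)
        assert (row["s1&s2"], row["s1&s3"], row["s2&s3"]) == (2, 1, 1)
        assert row["shared_all"] == 1

    def test_identical_and_disjoint_sets(self):
        same = self._collection({"s1": "abc", "s2": "abc", "s3": "abc"})
        assert cs.overlap_table(same).iloc[0]["shared_all"] == 3
        disj = self._collection({"s1": "ab", "s2": "cd", "s3": "ef"})
        row = cs.overlap_table(disj).iloc[0]
        assert row["shared_all"] == 0 and row["s1&s2"] == 0

    def test_intersections_are_monotone(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(40)]
        coll = self._collection(
            {s: set(rng.choice(genes, 20, replace=False)) for s in ("s1", "s2", "s3")}
        )
        row = cs.overlap_table(coll).iloc[0]
        three = row["shared_all"]
        for pair in ("s1&s2", "s1&s3", "s2&s3"):
            assert three <= row[pair]
        for s in ("s1", "s2", "s3"):
            assert row["s1&s2"] <= 20

    def test_ns_column_requires_ns_in_all_species(self):
        coll = self._collection(
            {"s1": "ab", "s2": "ab", "s3": "ab"},
            ns={"s1": "ab", "s2": "a", "s3": "ab"},
        )
        assert cs.overlap_table(coll).iloc[0]["shared_with_ns"] == 1


class TestTopCandidates:
    def _coll(self, flagged_ns, analyses=("outlier", "PRECYY", "TAVEYY")):
        sp = ("s1", "s2", "s3")
        sets = {}
        fns = {}
        for a in analyses:
            for s in sp:
                genes = frozenset(flagged_ns.get((a, s), ()))
                sets[(a, s)] = genes
                fns[(a, s)] = genes
        return cs.CandidateSetCollection(
            species_ids=sp, analyses=analyses, sets=sets, flagged_ns=fns,
            ns_genes={s: frozenset("abcdefgh") for s in sp},
        )

    def test_same_factor_in_all_species_included(self):
        coll = self._coll({("PRECYY", s): {"g"} for s in ("s1", "s2", "s3")})
        out = cs.top_candidates(coll)
        assert list(out["gene"]) == ["g"] and out["analyses"].iloc[0] == "PRECYY"

    def test_mixed_factors_excluded(self):
        coll = self._coll({
            ("PRECYY", "s1"): {"g"}, ("PRECYY", "s2"): {"g"}, ("TAVEYY", "s3"): {"g"},
        })
        assert len(cs.top_candidates(coll)) == 0

    def test_ns_missing_in_one_species_excluded(self):
        sp = ("s1", "s2", "s3")
        sets = {("outlier", s): frozenset("g") for s in sp}
        fns = {("outlier", s): frozenset("g" if s != "s3" else "") for s in sp}
        coll = cs.CandidateSetCollection(
            species_ids=sp, analyses=("outlier",), sets=sets, flagged_ns=fns,
            ns_genes={s: frozenset("g") for s in sp},
        )
        assert len(cs.top_candidates(coll)) == 0
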