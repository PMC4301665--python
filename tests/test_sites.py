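import numpy as np
import pytest
from hypothesis import given, strategies as st

from orthodiverge.codons import CODON_TO_AA, SENSE_CODONS, codon_neighbors
from orthodiverge.errors import ValidationError
from orthodiverge.seqio import Regions, TranscriptRecord
from orthodiverge.sites import (
    PairAlignment,
    align_cds_pair,
    build_pair_alignment,
    classify_cpg,
    classify_degeneracy,
    classify_sites,
    comparable_mask,
    ungapped_pair_alignment,
)


def cds_alignment(a: str, b: str) -> PairAlignment:
    """Gap-free CDS-only alignment (equal-length in-frame strings)."""
    assert len(a) == len(b) and len(a) % 3 == 0
    n = len(a)
    return PairAlignment(
        pair_id="t",
        a_aln=a,
        b_aln=b,
        region=np.full(n, "cds", dtype="<U5"),
        pos_a=np.arange(n),
        pos_b=np.arange(n),
        seq_a=a,
        seq_b=b,
    )


def utr_alignment(a_aln: str, b_aln: str) -> PairAlignment:
    n = len(a_aln)
    pos_a, pos_b = [], []
    ia = ib = 0
    for ca, cb in zip(a_aln, b_aln):
        pos_a.append(ia if ca != "-" else -1)
        pos_b.append(ib if cb != "-" else -1)
        ia += ca != "-"
        ib += cb != "-"
    return PairAlignment(
        pair_id="t",
        a_aln=a_aln,
        b_aln=b_aln,
        region=np.full(n, "utr5", dtype="<U5"),
        pos_a=np.array(pos_a),
        pos_b=np.array(pos_b),
        seq_a=a_aln.replace("-", ""),
        seq_b=b_aln.replace("-", ""),
    )


class TestAlignCdsPair:
    def test_identical_no_gaps(self):
        a, b = align_cds_pair("ATGGCGAAA", "ATGGCGAAA")
        assert a == b == "ATGGCGAAA"

    def test_codon_deletion_one_triple_gap(self):
        ca = "ATGGCGAAATGGTGC"
        cb = "ATGGCGTGGTGC"
        ga, gb = align_cds_pair(ca, cb, remove_gap_columns=False)
        assert ga == "ATGGCGAAATGGTGC"
        assert gb.count("-") == 3
        assert gb.replace("-", "") == cb
        i = gb.index("-")
        assert i % 3 == 0 and gb[i : i + 3] == "---"
        # after removal: equal lengths, in frame
        ra, rb = align_cds_pair(ca, cb)
        assert len(ra) == len(rb) == 12
        assert "-" not in ra + rb

    def test_synonymous_only_all_comparable(self):
        ca = "ATGGCTCGTGAT"
        cb = "ATGGCCCGCGAC"  # same protein, 3rd positions differ
        ga, gb = align_cds_pair(ca, cb)
        assert (ga, gb) == (ca, cb)
        aln = cds_alignment(ga, gb)
        assert comparable_mask(aln).all()

    def test_internal_stop_rejected(self):
        with pytest.raises(ValidationError, match="stop"):
            align_cds_pair("ATGTAAGCG", "ATGGCGGCG")

    def test_trailing_stop_stripped(self):
        a, b = align_cds_pair("ATGGCGTAA", "ATGGCGTGA")
        assert a == b == "ATGGCG"


class TestDegeneracy:
    def test_fourfold_glycine(self):
        aln = cds_alignment("GGA", "GGG")
        deg = classify_degeneracy(aln)
        assert deg[2] == "fourfold"

    def test_nd_second_position_phe(self):
        aln = cds_alignment("TTT", "TTT")
        deg = classify_degeneracy(aln)
        assert deg[1] == "nd"

    def test_ile_third_position_other(self):
        aln = cds_alignment("ATT", "ATT")
        deg = classify_degeneracy(aln)
        assert deg[2] == "other"

    def test_context_disagreement_goes_other(self):
        # 3rd position: GGx fourfold vs AGx (Ser/Arg split) -> prefix differs
        aln = cds_alignment("GGA", "AGA")
        deg = classify_degeneracy(aln)
        assert deg[2] == "other"

    def test_noncoding_label(self):
        aln = utr_alignment("ACGT", "ACGT")
        assert (classify_degeneracy(aln) == "noncoding").all()

    def test_exhaustive_vs_enumeration(self):
        """Degeneracy of every sense-codon pair column matches direct
        enumeration of the genetic code."""
        from orthodiverge.codons import FOURFOLD_PREFIXES, STOP_CODONS

        rng = np.random.default_rng(0)
        sample = [(a, b) for a in SENSE_CODONS for b in SENSE_CODONS]
        for a, b in sample:
            aln = cds_alignment(a, b)
            deg = classify_degeneracy(aln)
            for pos in range(3):
                # oracle: enumerate neighbours for both codons
                def all_nonsyn(c):
                    changes = [
                        c[:pos] + nt + c[pos + 1 :]
                        for nt in "ACGT"
                        if nt != c[pos]
                    ]
                    sense = [x for x in changes if x not in STOP_CODONS]
                    return bool(sense) and all(
                        CODON_TO_AA[x] != CODON_TO_AA[c] for x in sense
                    )

                expect_nd = all_nonsyn(a) and all_nonsyn(b)
                expect_ff = (
                    pos == 2 and a[:2] == b[:2] and a[:2] in FOURFOLD_PREFIXES
                )
                if expect_ff:
                    assert deg[pos] == "fourfold", (a, b, pos)
                elif expect_nd:
                    assert deg[pos] == "nd", (a, b, pos)
                else:
                    assert deg[pos] == "other", (a, b, pos)


class TestCpG:
    def test_union_over_sequences(self):
        aln = utr_alignment("ACGT", "ATGT")
        cpg = classify_cpg(aln)
        assert cpg[1]  # C of CG in seq_a
        assert cpg[2]  # G of CG in seq_a
        assert not cpg[0] and not cpg[3]

    def test_all_a_no_cpg(self):
        aln = utr_alignment("AAAA", "AAAA")
        assert not classify_cpg(aln).any()

    def test_overlapping_cg_all_flagged(self):
        aln = utr_alignment("CGCG", "CGCG")
        assert classify_cpg(aln).all()

    def test_symmetric_in_sequences(self):
        a, b = "ACGTTGCA", "TTTTCGTA"
        aln1 = utr_alignment(a, b)
        aln2 = utr_alignment(b, a)
        assert (classify_cpg(aln1) == classify_cpg(aln2)).all()

    def test_both_mode_is_intersection(self):
        aln = utr_alignment("ACGT", "ATGT")
        assert not classify_cpg(aln, mode="both").any()


class TestBuildPairAlignment:
    def make_pair(self):
        a = TranscriptRecord(
            "a", "CCACGATGGCTCGTGATTAAGTT",
            Regions((0, 5), (5, 20), (20, 23)),
        )
        b = TranscriptRecord(
            "b", "CTACGATGGCCCGCGACTAAGCT",
            Regions((0, 5), (5, 20), (20, 23)),
        )
        return a, b

    def test_regions_concatenated(self):
        a, b = self.make_pair()
        aln = build_pair_alignment(a, b)
        assert set(aln.region) == {"utr5", "cds", "utr3"}
        # removing gaps recovers the input (stop codon stripped from CDS)
        assert aln.a_aln.replace("-", "") == a.utr5 + a.cds[:-3] + a.utr3
        # cds block in frame
        assert (aln.region == "cds").sum() % 3 == 0

    def test_partition_counts_conserve(self):
        a, b = self.make_pair()
        aln = build_pair_alignment(a, b)
        part = classify_sites(aln)
        cds = aln.region == "cds"
        nd = (part.degeneracy == "nd") & part.comparable
        ff = (part.degeneracy == "fourfold") & part.comparable
        other = (part.degeneracy == "other") & part.comparable
        assert nd.sum() + ff.sum() + other.sum() == (cds & part.comparable).sum()

    def test_cds_first_base_uses_utr_neighbor(self):
        # utr5 ends in C, cds starts with G: CpG context spans the boundary
        a = TranscriptRecord("a", "ACGTGCATGGCTTAA", Regions((0, 3), (3, 15), (15, 15)))
        # cds = TGCATGGCTTAA? keep simple: check no crash and flags computed
        aln = build_pair_alignment(a, a, pair_id="self")
        cpg = classify_cpg(aln)
        assert cpg[1] and cpg[2]
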