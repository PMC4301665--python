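import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from orthodiverge.codons import SENSE_CODONS
from orthodiverge.errors import SaturationError, ValidationError
from orthodiverge.kaks import (
    KaKsResult,
    bin_kaks,
    estimate_kappa,
    fisher_pvalue,
    jukes_cantor,
    ng86_differences,
    ng86_kaks,
    ng86_sites,
    pathway_counts,
    sliding_window_scan,
    yn_kaks,
)
from oracles import oracle_differences, oracle_kaks, oracle_sites


class TestNg86Sites:
    @pytest.mark.parametrize(
        "codon,s,n",
        [("TTT", 1 / 3, 8 / 3), ("GGG", 1.0, 2.0), ("ATG", 0.0, 3.0)],
    )
    def test_hand_examples(self, codon, s, n):
        got = ng86_sites(codon)
        assert got[0] == pytest.approx(s)
        assert got[1] == pytest.approx(n)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValidationError):
            ng86_sites("TAA")

    def test_all_61_codons_match_oracle(self):
        for codon in SENSE_CODONS:
            assert ng86_sites(codon) == pytest.approx(oracle_sites(codon))

    def test_sites_sum_to_three(self):
        for codon in SENSE_CODONS:
            s, n = ng86_sites(codon)
            assert s + n == pytest.approx(3.0)


class TestNg86Differences:
    @pytest.mark.parametrize(
        "a,b,sd,nd",
        [("TTT", "TTC", 1, 0), ("TTT", "GTA", 0.5, 1.5), ("TTT", "TTT", 0, 0)],
    )
    def test_hand_examples(self, a, b, sd, nd):
        assert ng86_differences(a, b) == pytest.approx((sd, nd))

    def test_symmetry_and_triangle(self):
        rng = np.random.default_rng(2)
        for _ in range(300):
            a = SENSE_CODONS[rng.integers(61)]
            b = SENSE_CODONS[rng.integers(61)]
            sd_ab, nd_ab = ng86_differences(a, b)
            sd_ba, nd_ba = ng86_differences(b, a)
            assert (sd_ab, nd_ab) == pytest.approx((sd_ba, nd_ba))
            hamming = sum(x != y for x, y in zip(a, b))
            assert sd_ab + nd_ab >= hamming - 1e-12

    def test_all_pairs_match_oracle(self):
        for a in SENSE_CODONS:
            for b in SENSE_CODONS:
                assert ng86_differences(a, b) == pytest.approx(
                    oracle_differences(a, b)
                ), (a, b)

    def test_ts_tv_split_consistent(self):
        pc = pathway_counts("TTT", "GTA")
        assert pc.sd_ts + pc.sd_tv == pytest.approx(pc.sd)
        assert pc.nd_ts + pc.nd_tv == pytest.approx(pc.nd)


class TestNg86KaKs:
    def test_gga_analytic_example(self):
        pairs = [("GGA", "GGC")] * 10 + [("GGA", "GGA")] * 90
        r = ng86_kaks(pairs)
        assert r.S == pytest.approx(100.0)
        assert r.N == pytest.approx(200.0)
        assert r.Sd == pytest.approx(10.0)
        assert r.Nd == pytest.approx(0.0)
        assert r.ks == pytest.approx(0.10733, abs=1e-5)
        assert r.ka == 0.0
        assert r.omega == 0.0

    def test_identical_zero(self):
        r = ng86_kaks([("ATG", "ATG"), ("GCT", "GCT")])
        assert r.ka == r.ks == 0.0
        assert r.omega is None and "ks_zero" in r.flags

    def test_saturation_flagged(self):
        # triple-substitution nonsynonymous codon pairs drive pN past 3/4
        pairs = [("ATG", "CCC")] * 50
        r = ng86_kaks(pairs)
        assert r.ka is None and "ka_saturated" in r.flags

    def test_matches_oracle_on_random_alignments(self, random_codon_pairs):
        for n in (1, 3, 10, 30):
            for _ in range(40):
                pairs = random_codon_pairs(n)
                mine = ng86_kaks(pairs)
                try:
                    ref = oracle_kaks(pairs)
                except ValueError:
                    continue
                assert mine.S == pytest.approx(ref["S"], abs=1e-9)
                assert mine.N == pytest.approx(ref["N"], abs=1e-9)
                assert mine.Sd == pytest.approx(ref["Sd"], abs=1e-9)
                assert mine.Nd == pytest.approx(ref["Nd"], abs=1e-9)
                if mine.ks is not None:
                    assert mine.ks == pytest.approx(ref["ks"], abs=1e-9)
                if mine.ka is not None:
                    assert mine.ka == pytest.approx(ref["ka"], abs=1e-9)


class TestYn:
    def test_identical_zero_any_kappa(self):
        for kappa in (0.5, 1.0, 5.0):
            r = yn_kaks([("ATG", "ATG"), ("GGA", "GGA")], kappa=kappa)
            assert r.ka == r.ks == 0.0

    def test_reduces_to_ng86_at_kappa_one_uniform(self, random_codon_pairs):
        uniform = np.full((3, 4), 0.25)
        for _ in range(25):
            pairs = random_codon_pairs(120)
            r_yn = yn_kaks(pairs, kappa=1.0, freqs=uniform)
            r_ng = ng86_kaks(pairs)
            assert r_yn.S == pytest.approx(r_ng.S, rel=1e-9)
            assert r_yn.N == pytest.approx(r_ng.N, rel=1e-9)

    def test_kappa_fallback_flag(self):
        r = yn_kaks([("ATG", "ATG")])
        assert "kappa_fallback" in r.flags

    def test_kappa_estimated_from_fourfold_sites(self):
        # many fourfold transitions, few transversions -> kappa > 1
        pairs = [("GGA", "GGG")] * 30 + [("GGA", "GGC")] * 5 + [("GGA", "GGA")] * 200
        k = estimate_kappa(pairs)
        assert k is not None and k > 1.5


class TestFisher:
    def test_balanced_table(self):
        r = KaKsResult("x", "NG86", S=2, N=2, Sd=1, Nd=1, ks=0, ka=0, omega=None)
        assert fisher_pvalue(r) == pytest.approx(1.0)

    def test_extreme_table_closed_form(self):
        r = KaKsResult("x", "NG86", S=10, N=10, Sd=0, Nd=10, ks=0, ka=0, omega=None)
        assert fisher_pvalue(r) == pytest.approx(2 / math.comb(20, 10), abs=1e-9)

    def test_negative_cell_rejected(self):
        r = KaKsResult("x", "NG86", S=5, N=5, Sd=8, Nd=0, ks=0, ka=0, omega=None)
        with pytest.raises(ValidationError):
            fisher_pvalue(r)


class TestBinning:
    def make(self, omega, ks=0.1):
        return KaKsResult(
            "x", "YN", S=100, N=200, Sd=10, Nd=5,
            ks=ks, ka=None if omega is None else omega * ks,
            omega=omega,
        )

    def test_one_per_bin(self):
        res = [self.make(w) for w in (2.5, 1.5, 0.7, 0.2)]
        bins = bin_kaks(res)
        assert bins[">2"] == bins["(1,2]"] == bins["(0.5,1]"] == bins["<=0.5"] == 1

    def test_boundary_omega_one(self):
        bins = bin_kaks([self.make(1.0)])
        assert bins["(0.5,1]"] == 1

    def test_undefined_reported_separately(self):
        res = [self.make(None), self.make(0.3)]
        bins = bin_kaks(res)
        assert bins["undefined"] == 1
        assert bins["<=0.5"] == 1


class TestSlidingWindow:
    def synonymous_pairs(self, n):
        # synonymous difference every 5th codon (sparse enough to avoid
        # saturating the within-window proportion)
        return [("GGA", "GGG") if i % 5 == 0 else ("GGA", "GGA") for i in range(n)]

    def test_window_count_300bp(self):
        pairs = self.synonymous_pairs(100)  # 300 bp
        scan = sliding_window_scan(pairs, window_len=57, step=6)
        assert len(scan.windows) == 41

    def test_synonymous_only_all_zero_omega(self):
        scan = sliding_window_scan(self.synonymous_pairs(100))
        assert all(w.omega == 0.0 for w in scan.windows)
        assert not any(w.flagged for w in scan.windows)

    def test_short_alignment_single_window(self):
        scan = sliding_window_scan(self.synonymous_pairs(10), window_len=57, step=6)
        assert len(scan.windows) == 1
        assert (scan.windows[0].start, scan.windows[0].end) == (0, 30)

    def test_frame_validation(self):
        with pytest.raises(ValidationError):
            sliding_window_scan(self.synonymous_pairs(30), window_len=50, step=6)

    def test_scan_aggregates_to_whole_gene(self):
        # non-overlapping windows (step == window) partition the codons:
        # summed raw counts equal the whole-gene counts
        rng = np.random.default_rng(4)
        pairs = [
            (SENSE_CODONS[rng.integers(61)], SENSE_CODONS[rng.integers(61)])
            for _ in range(60)
        ]
        whole = ng86_kaks(pairs)
        parts = [ng86_kaks(pairs[i : i + 10]) for i in range(0, 60, 10)]
        assert sum(p.S for p in parts) == pytest.approx(whole.S)
        assert sum(p.Sd for p in parts) == pytest.approx(whole.Sd)
        assert sum(p.Nd for p in parts) == pytest.approx(whole.Nd)

    def test_localizes_implanted_cluster(self):
        from orthodiverge.simulate import (
            SimConfig,
            implant_selection_window,
            simulate_ortholog_pairs,
        )
        from orthodiverge.sites import codon_pairs, ungapped_pair_alignment

        cfg = SimConfig(n_pairs=1, cds_codons=100, utr5_len=0, utr3_len=0,
                        omega=0.0, t=0.15, n_decoys=0, seed=21)
        A, B, _ = simulate_ortholog_pairs(cfg)
        (a2, b2), implant = implant_selection_window((A[0], B[0]), n_nonsyn=5, rng=22)
        aln = ungapped_pair_alignment(a2, b2)
        scan = sliding_window_scan(codon_pairs(aln))
        best = scan.max_omega_window()
        # stop codon of the CDS is excluded from the codon-pair coordinates
        assert best.start < implant["cds_end"] + 6
        assert best.end > implant["cds_start"] - 6
        assert best.flagged or best.omega is None


class TestJukesCantor:
    def test_values(self):
        assert jukes_cantor(0.0) == 0.0
        assert jukes_cantor(0.1) == pytest.approx(-0.75 * math.log(1 - 0.4 / 3))

    def test_saturation(self):
        with pytest.raises(SaturationError):
            jukes_cantor(0.75)
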