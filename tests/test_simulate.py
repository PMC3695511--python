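"""Determinism and calibration of the WGA simulator."""

import numpy as np
import pandas as pd
import pytest

import scpem
from scpem.cnv import fit_gc_trend
from scpem.pairs import build_refined_map
from scpem.simulate import (WGAProfile, simulate_bin_counts,
                            simulate_read_pairs, simulate_sister_division,
                            simulate_snp_counts, simulate_truth_genome)


class TestTruthGenome:
    def test_del_sv_lowers_cn_over_its_span(self, small_truth):
        seg = small_truth.segments
        inside = seg[(seg["chrom"] == "chr1") & (seg["start"] == 10_000_000)]
        assert inside.iloc[0]["end"] == 18_000_000
        assert inside.iloc[0][["cn_a", "cn_b"]].sum() == 1
        assert small_truth.cn_at("chr2", np.array([21_000_000]))[0] == 3

    def test_deterministic_for_fixed_seed(self):
        a = simulate_truth_genome(seed=5)
        b = simulate_truth_genome(seed=5)
        pd.testing.assert_frame_equal(a.segments, b.segments)
        pd.testing.assert_frame_equal(a.svs, b.svs)
        pd.testing.assert_frame_equal(a.snps, b.snps)

    def test_balanced_itx_leaves_cn_background(self):
        t = simulate_truth_genome(sv_spec=[
            {"sig_class": "ITX", "chrom1": "chr1", "pos1": 10_000_000,
             "chrom2": "chr2", "pos2": 30_000_000}], seed=1)
        assert (t.segments["cn_a"] + t.segments["cn_b"] == 2).all()

    def test_overlapping_cn_events_rejected(self):
        with pytest.raises(ValueError):
            simulate_truth_genome(sv_spec=[
                {"sig_class": "DEL", "chrom1": "chr1", "pos1": 1_000_000,
                 "span": 5_000_000},
                {"sig_class": "TD", "chrom1": "chr1", "pos1": 3_000_000,
                 "span": 5_000_000}], seed=1)

    def test_psi_is_length_weighted_mean_cn(self, small_truth):
        seg = small_truth.segments
        w = (seg["end"] - seg["start"]).to_numpy()
        cn = (seg["cn_a"] + seg["cn_b"]).to_numpy()
        assert small_truth.psi == pytest.approx((w * cn).sum() / w.sum())


class TestBinCounts:
    def test_unbiased_depth_matches_analytic_mean(self):
        truth = simulate_truth_genome(n_svs=0, seed=2)
        bins = simulate_bin_counts(truth, WGAProfile.none(), 200, seed=3)
        full = bins[bins["end"] - bins["start"] == 10_000]
        m = full["count_cell"].mean()
        se = full["count_cell"].std() / np.sqrt(len(full))
        assert abs(m - 200) < 3 * se + 0.5

    def test_base_level_breadth(self):
        # breadth is a base-level genome fraction; with ~1-kb amplicons a
        # 10-kb bin mixes amplified and silent tracts, so counts scale with
        # the amplified fraction while most bins stay nonzero
        truth = simulate_truth_genome(n_svs=0, seed=2)
        wga = WGAProfile.picoplex().with_overrides(
            bias_sd=0.0, gc_lin=0.0, gc_quad=0.0, dispersion=0.0)
        bins = simulate_bin_counts(truth, wga, 100, seed=3)
        # mean count is renormalised by breadth: amplified loci are deeper
        assert bins["count_cell"].mean() == pytest.approx(100, rel=0.05)
        # per-bin amplified fraction has mean = breadth -> relative variance
        # of counts far exceeds Poisson
        rel_sd = bins["count_cell"].std() / bins["count_cell"].mean()
        assert rel_sd > 0.3

    def test_gc_bias_visible_then_corrected(self):
        truth = simulate_truth_genome(n_svs=0, seed=4)
        wga = WGAProfile.none().with_overrides(gc_lin=-3.0)
        bins = simulate_bin_counts(truth, wga, 200, seed=5)
        kept = scpem.filter_bins(bins)
        raw = scpem.compute_logr(bins, kept)
        gc = raw.kept_bins["gc"].to_numpy()
        slope_raw = np.polyfit(gc, raw.logr, 1)[0]
        assert abs(slope_raw) > 1.0
        corrected = scpem.gc_correct_and_center(raw)
        refit = fit_gc_trend(corrected.logr, gc)
        assert np.max(np.abs(refit)) < 0.05

    def test_deterministic(self):
        truth = simulate_truth_genome(seed=6)
        a = simulate_bin_counts(truth, WGAProfile.mda(), 100, seed=7)
        b = simulate_bin_counts(truth, WGAProfile.mda(), 100, seed=7)
        pd.testing.assert_frame_equal(a, b)


class TestReadPairs:
    def test_single_del_recovered_at_truth_breakpoints(self):
        truth = simulate_truth_genome(sv_spec=[
            {"sig_class": "DEL", "chrom1": "chr1", "pos1": 10_000_000,
             "span": 4_000_000}], seed=8)
        wga = WGAProfile.none()
        pairs = simulate_read_pairs(truth, wga, depth=200, seed=9)
        m = build_refined_map(pairs)
        assert len(m) == 1
        s = m.signatures[0]
        assert s.sig_class.value == "DEL"
        assert abs(s.intervalA[1] - 10_000_000) < 600
        assert abs(s.intervalB[0] - 14_000_000) < 600

    def test_same_seed_identical_table(self):
        truth = simulate_truth_genome(seed=10)
        a = simulate_read_pairs(truth, WGAProfile.picoplex(), seed=11)
        b = simulate_read_pairs(truth, WGAProfile.picoplex(), seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_mda_artefacts_inversion_dominated(self):
        truth = simulate_truth_genome(n_svs=0, seed=12)
        pairs = simulate_read_pairs(truth, WGAProfile.mda(),
                                    n_artefact_signatures=2_000, seed=13)
        m = build_refined_map(pairs)
        sigs = [s for s in m.signatures if s.support >= 2]
        inv = sum(s.sig_class.value == "INV" for s in sigs)
        assert inv / len(sigs) > 0.9

    def test_canonical_ordering(self):
        truth = simulate_truth_genome(seed=14)
        pairs = simulate_read_pairs(truth, WGAProfile.picoplex(), seed=15)
        k1 = list(zip(pairs["chrom1"], pairs["pos1"]))
        k2 = list(zip(pairs["chrom2"], pairs["pos2"]))
        assert all(a <= b for a, b in zip(k1, k2))


class TestSnpCounts:
    def test_het_cn2_mean_baf_half(self):
        truth = simulate_truth_genome(n_svs=0, seed=16)
        wga = WGAProfile.none()
        snps = simulate_snp_counts(truth, wga, mean_depth=40, seed=17)
        rec = scpem.compute_baf(snps)
        het = (truth.snps["genotype"] == "AB").to_numpy()
        sel = het & (rec["depth"].to_numpy() >= 10)
        baf = rec.loc[sel, "baf"]
        se = baf.std() / np.sqrt(len(baf))
        assert abs(baf.mean() - 0.5) < 3 * se

    def test_cn1_baf_is_zero_or_one(self):
        truth = simulate_truth_genome(sv_spec=[
            {"sig_class": "DEL", "chrom1": "chr1", "pos1": 5_000_000,
             "span": 40_000_000}], seed=18)
        snps = simulate_snp_counts(truth, WGAProfile.none(), mean_depth=40,
                                   seed=19)
        rec = scpem.compute_baf(snps)
        het = (truth.snps["genotype"] == "AB").to_numpy()
        inside = ((rec["chrom"] == "chr1") & (rec["pos"] >= 5_000_000)
                  & (rec["pos"] < 45_000_000)).to_numpy()
        sel = het & inside & (rec["depth"].to_numpy() > 0)
        baf = rec.loc[sel, "baf"].to_numpy()
        assert np.all((baf == 0.0) | (baf == 1.0))

    def test_full_dropout_reads_homozygous(self):
        truth = simulate_truth_genome(n_svs=0, seed=20)
        wga = WGAProfile.none().with_overrides(ado_rate=1.0)
        snps = simulate_snp_counts(truth, wga, mean_depth=40, seed=21)
        assert (snps["a_reads"] + snps["b_reads"] == 0).all()
        # dropping a single haplotype keeps the other one readable
        half = WGAProfile.none().with_overrides(ado_rate=0.5)
        snps = simulate_snp_counts(truth, half, mean_depth=40, seed=22)
        rec = scpem.compute_baf(snps)
        het = (truth.snps["genotype"] == "AB").to_numpy()
        sel = het & (rec["depth"].to_numpy() >= 10)
        extreme = ((rec.loc[sel, "baf"] <= 0.01) |
                   (rec.loc[sel, "baf"] >= 0.99)).mean()
        assert 0.4 < extreme < 0.75  # two one-sided dropouts of rate 0.5


class TestSisterDivision:
    def test_reciprocal_event_cns(self):
        parent = simulate_truth_genome(n_svs=0, seed=23)
        a, b = simulate_sister_division(parent, [
            {"chrom": "chr1", "start": 5_000_000, "end": 45_000_000,
             "kind": "reciprocal", "k": 1}], seed=24)
        assert a.cn_at("chr1", np.array([20_000_000]))[0] == 3
        assert b.cn_at("chr1", np.array([20_000_000]))[0] == 1

    def test_unbalanced_gain_touches_one_daughter(self):
        parent = simulate_truth_genome(n_svs=0, seed=25)
        a, b = simulate_sister_division(parent, [
            {"chrom": "chr2", "start": 5_000_000, "end": 15_000_000,
             "kind": "unbalanced_gain"}], seed=26)
        assert a.cn_at("chr2", np.array([10_000_000]))[0] == 3
        assert b.cn_at("chr2", np.array([10_000_000]))[0] == 2

    def test_empty_events_identical_daughters(self):
        parent = simulate_truth_genome(seed=27)
        a, b = simulate_sister_division(parent, [], seed=28)
        pd.testing.assert_frame_equal(a.segments, parent.segments)
        pd.testing.assert_frame_equal(a.segments, b.segments)

    def test_negative_cn_rejected(self):
        parent = simulate_truth_genome(n_svs=0, seed=29)
        with pytest.raises(ValueError):
            simulate_sister_division(parent, [
                {"chrom": "chr1", "start": 0, "end": 10_000_000,
                 "kind": "reciprocal", "k": 3}], seed=30)


class TestProfiles:
    def test_spectrum_must_sum_to_one(self):
        with pytest.raises(ValueError):
            WGAProfile.mda().with_overrides(
                artefact_spectrum={"INV": 0.5, "TD": 0.1})

    def test_by_name(self):
        assert WGAProfile.by_name("MDA").name == "MDA"
        with pytest.raises(ValueError):
            WGAProfile.by_name("bulk")
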