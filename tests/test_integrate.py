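"""Map benchmarking, bait capture, artefact flagging and sister-cell analysis."""

import numpy as np
import pytest

from scpem.integrate import (bait_capture, breakpoint_cn_concordance,
                             cn_concordance, compute_ppv, compute_sensitivity,
                             flag_pcr_pileup_gains, match_maps,
                             reciprocal_events)
from scpem.pairs import (ITX_SPAN, PairedEndMap, RearrangementSignature,
                         SignatureClass)
from scpem.pcf import Segment


def sig(cls, posA, posB, support=5, chromA="chr1", chromB=None, width=200):
    cls = SignatureClass(cls)
    chromB = chromB or chromA
    span = ITX_SPAN if cls is SignatureClass.ITX else posB - posA
    return RearrangementSignature(cls, chromA, (posA, posA + width), chromB,
                                  (posB, posB + width), span, support,
                                  [f"{cls.value}{posA}_{i}" for i in range(support)])


class TestMatching:
    def test_greedy_one_to_one(self):
        ref = [sig("DEL", 100_000, 200_000)]
        query = [sig("DEL", 100_500, 200_500), sig("DEL", 102_000, 202_000)]
        matches = match_maps(query, ref, tolerance=10_000)
        matched = [m for m in matches if m.reference is not None]
        assert len(matched) == 1  # nearer query wins, reference used once
        assert matched[0].query is query[0]

    def test_class_and_chrom_must_agree(self):
        ref = [sig("TD", 100_000, 200_000)]
        assert match_maps([sig("DEL", 100_000, 200_000)], ref)[0].reference is None
        ref2 = [sig("DEL", 100_000, 200_000, chromA="chr2")]
        assert match_maps([sig("DEL", 100_000, 200_000)], ref2)[0].reference is None


class TestPpv:
    def test_two_of_three_match(self):
        ref = [sig("DEL", 100_000, 200_000), sig("DEL", 500_000, 700_000)]
        query = [sig("DEL", 100_200, 200_200),
                 sig("DEL", 500_300, 700_300),
                 sig("DEL", 2_000_000, 2_300_000)]
        ppv = compute_ppv(PairedEndMap(signatures=query),
                          PairedEndMap(signatures=ref), thresholds=[2],
                          match_tolerance=10_000)
        assert ppv.loc[2, "DEL"] == pytest.approx(2 / 3)

    def test_all_match_gives_one(self):
        q = [sig("TD", 100_000, 300_000)]
        ppv = compute_ppv(PairedEndMap(signatures=q),
                          PairedEndMap(signatures=q), thresholds=[2])
        assert ppv.loc[2, "TD"] == 1.0

    def test_empty_threshold_is_nan_not_zero(self):
        q = [sig("DEL", 100_000, 200_000, support=3)]
        ppv = compute_ppv(PairedEndMap(signatures=q), PairedEndMap(signatures=[]),
                          thresholds=[2, 10])
        assert ppv.loc[2, "DEL"] == 0.0
        assert np.isnan(ppv.loc[10, "DEL"])


class TestSensitivity:
    def test_fraction_recovered(self):
        validated = [sig("DEL", i * 1_000_000, i * 1_000_000 + 200_000)
                     for i in range(10)]
        query = [sig("DEL", i * 1_000_000 + 100, i * 1_000_000 + 200_100)
                 for i in range(6)]
        sens = compute_sensitivity(PairedEndMap(signatures=query), validated,
                                   thresholds=[2])
        assert sens.loc[2] == pytest.approx(0.6)

    def test_empty_query_is_zero(self):
        validated = [sig("DEL", 100_000, 300_000)]
        sens = compute_sensitivity(PairedEndMap(signatures=[]), validated,
                                   thresholds=[2, 5])
        assert (sens == 0).all()

    def test_support_seven_recovered_up_to_seven(self):
        validated = [sig("DEL", 100_000, 300_000)]
        query = [sig("DEL", 100_100, 300_100, support=7)]
        sens = compute_sensitivity(PairedEndMap(signatures=query), validated,
                                   thresholds=range(2, 11))
        assert (sens.loc[2:7] == 1.0).all()
        assert (sens.loc[8:] == 0.0).all()

    def test_empty_validated_set_errors(self):
        with pytest.raises(ValueError):
            compute_sensitivity(PairedEndMap(signatures=[]), [])

    def test_nonincreasing_on_random_maps(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            validated = [sig("DEL", int(p), int(p) + 100_000)
                         for p in rng.integers(0, 40_000_000, 8)]
            query = [sig("DEL", int(p) + int(rng.integers(0, 5_000)),
                         int(p) + 100_000, support=int(rng.integers(1, 15)))
                     for p in rng.integers(0, 40_000_000, 8)]
            sens = compute_sensitivity(PairedEndMap(signatures=query), validated)
            assert (np.diff(sens.to_numpy()) <= 1e-12).all()


class TestBaitCapture:
    def test_radius_rule_and_consistency(self):
        bps = {"chr1": np.array([[1_000_000.0, -0.8]])}
        near = sig("DEL", 1_030_000, 2_000_000)   # 30 kb from breakpoint
        far = sig("DEL", 1_070_000, 2_000_000)    # 70 kb away on both sides
        m = PairedEndMap(signatures=[near, far])
        captured = bait_capture(m, bps, radius=50_000)
        assert [c["signature"] for c in captured] == [near]
        assert captured[0]["consistent"] is True  # DEL with logR drop

    def test_td_needs_rise(self):
        bps = {"chr1": np.array([[1_000_000.0, -0.5]])}
        m = PairedEndMap(signatures=[sig("TD", 1_010_000, 1_200_000)])
        captured = bait_capture(m, bps, radius=50_000)
        assert captured[0]["consistent"] is False

    def test_inv_has_no_expected_sign(self):
        bps = {"chr1": np.array([[1_000_000.0, 0.5]])}
        m = PairedEndMap(signatures=[sig("INV", 1_010_000, 1_200_000)])
        assert bait_capture(m, bps, radius=50_000)[0]["consistent"] is None

    def test_never_captures_beyond_radius(self):
        rng = np.random.default_rng(31)
        bps = {"chr1": np.column_stack([rng.integers(0, 50_000_000, 5),
                                        rng.normal(0, 1, 5)]).astype(float)}
        sigs = [sig("DEL", int(p), int(p) + 300_000)
                for p in rng.integers(0, 50_000_000, 50)]
        captured = bait_capture(PairedEndMap(signatures=sigs), bps,
                                radius=50_000)
        for c in captured:
            s = c["signature"]
            d = min(min(abs(s.intervalA[0] - p), abs(s.intervalA[1] - p),
                        abs(s.intervalB[0] - p), abs(s.intervalB[1] - p))
                    for p in bps["chr1"][:, 0])
            assert d <= 50_000


class TestPileupFlags:
    def _gain(self):
        return Segment(chrom="chr1", start_bp=1_000_000, end_bp=1_100_000,
                       first_bin=0, last_bin=10, mean_logr=0.6, n_bins=11, cn=3)

    def test_tiny_flanking_tds_flag_artefact(self):
        tds = [sig("TD", 990_000 + i * 3_000, 992_000 + i * 3_000)
               for i in range(3)]
        flags = flag_pcr_pileup_gains([self._gain()],
                                      PairedEndMap(signatures=tds))
        assert flags[0]["artefact"] is True

    def test_corroborating_td_clears_flag(self):
        tds = [sig("TD", 995_000, 997_000), sig("TD", 1_002_000, 1_004_000),
               sig("TD", 999_000, 1_101_000)]  # spans the whole gain
        flags = flag_pcr_pileup_gains([self._gain()],
                                      PairedEndMap(signatures=tds))
        assert flags[0]["artefact"] is False
        assert flags[0]["corroborated"] is True

    def test_no_signatures_not_flagged(self):
        flags = flag_pcr_pileup_gains([self._gain()],
                                      PairedEndMap(signatures=[]))
        assert flags[0]["artefact"] is False


class TestConcordance:
    def test_breakpoint_cn_match_rules(self):
        segs = [Segment("chr1", 5_060_000, 9_000_000, 0, 10, 0.58, 11, cn=3)]
        ev = {"chrom": "chr1", "pos": 5_000_000, "cn": 3}
        assert breakpoint_cn_concordance(segs, [ev]) == 1.0
        assert breakpoint_cn_concordance(segs, [{**ev, "cn": 4}]) == 0.0
        segs_far = [Segment("chr1", 5_250_000, 9_000_000, 0, 10, 0.58, 11, cn=3)]
        assert breakpoint_cn_concordance(segs_far, [ev]) == 0.0
        with pytest.raises(ValueError):
            breakpoint_cn_concordance(segs, [])

    def test_cn_concordance(self):
        a = np.array([2, 2, 3, 3, 1, 2, 2, 2, 2, 2])
        assert cn_concordance(a, a) == 1.0
        b = a.copy()
        b[:3] = 5
        assert cn_concordance(a, b) == pytest.approx(0.7)
        with pytest.raises(ValueError):
            cn_concordance(a[:0], b[:0])


class TestReciprocalEvents:
    @staticmethod
    def consensus(chrom, start, end):
        return 2

    def seg(self, start, end, cn, chrom="chr1"):
        return Segment(chrom, start, end, 0, 0, 0.0, 10, cn=cn)

    def test_opposite_deviation_is_reciprocal(self):
        a = [self.seg(0, 10_000_000, 2), self.seg(10_000_000, 20_000_000, 3),
             self.seg(20_000_000, 50_000_000, 2)]
        b = [self.seg(0, 10_000_000, 2), self.seg(10_000_000, 20_000_000, 1),
             self.seg(20_000_000, 50_000_000, 2)]
        events = reciprocal_events(a, b, self.consensus)
        assert len(events) == 1
        assert events[0].kind == "reciprocal"
        assert (events[0].cn_cell_a, events[0].cn_cell_b) == (3, 1)

    def test_one_sided_gain_is_unbalanced(self):
        a = [self.seg(0, 10_000_000, 2), self.seg(10_000_000, 20_000_000, 3),
             self.seg(20_000_000, 50_000_000, 2)]
        b = [self.seg(0, 50_000_000, 2)]
        events = reciprocal_events(a, b, self.consensus)
        assert [e.kind for e in events] == ["unbalanced_gain"]
        assert (events[0].cn_cell_a, events[0].cn_cell_b) == (3, 2)

    def test_identical_cells_give_no_events(self):
        a = [self.seg(0, 50_000_000, 2)]
        assert reciprocal_events(a, a, self.consensus) == []
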