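"""Discordant-pair classification, clustering, filtering and thresholding."""

import numpy as np
import pandas as pd
import pytest

from scpem.pairs import (FilterPanel, RearrangementSignature, SignatureClass,
                         build_reference_map, build_refined_map, classify_pair,
                         classify_pairs, cluster_pairs, merge_intervals,
                         threshold_map)


def mk_pair(pair_id, c1, p1, s1, c2, p2, s2, mapq1=60, mapq2=60, alt=False):
    return {"pair_id": pair_id, "chrom1": c1, "pos1": p1, "strand1": s1,
            "chrom2": c2, "pos2": p2, "strand2": s2, "mapq1": mapq1,
            "mapq2": mapq2, "alt_concordant": alt}


def pair_frame(*pairs):
    return pd.DataFrame(list(pairs))


class TestClassify:
    @pytest.mark.parametrize("p, expected", [
        (mk_pair("a", "chr1", 10_000, "+", "chr1", 60_000, "-"), "DEL"),
        (mk_pair("b", "chr1", 10_000, "-", "chr1", 60_000, "+"), "TD"),
        (mk_pair("c", "chr1", 10_000, "+", "chr2", 5_000, "-"), "ITX"),
        (mk_pair("d", "chr1", 10_000, "+", "chr1", 60_000, "+"), "INV"),
        (mk_pair("e", "chr1", 10_000, "-", "chr1", 60_000, "-"), "INV"),
        (mk_pair("f", "chr1", 10_000, "+", "chr1", 10_300, "-"), "CONCORDANT"),
        # short-insert forward-reverse treated as concordant
        (mk_pair("g", "chr1", 10_000, "+", "chr1", 10_050, "-"), "CONCORDANT"),
    ])
    def test_orientation_rules(self, p, expected):
        got = classify_pair(p, insert_min=200, insert_max=600)
        assert got.value == expected

    def test_bad_strand_rejected(self):
        with pytest.raises(ValueError):
            classify_pairs(pair_frame(
                mk_pair("a", "chr1", 1, "x", "chr1", 2, "-")))


class TestCluster:
    def test_nearby_same_class_pairs_merge(self):
        df = pair_frame(
            mk_pair("a", "chr1", 10_000, "+", "chr1", 60_000, "-"),
            mk_pair("b", "chr1", 10_300, "+", "chr1", 60_300, "-"))
        sigs = cluster_pairs(df, classify_pairs(df), join_distance=1_000)
        assert len(sigs) == 1
        assert sigs[0].support == 2
        assert sigs[0].intervalA == (10_000, 10_300)
        assert sorted(sigs[0].pair_ids) == ["a", "b"]

    def test_different_classes_never_merge(self):
        df = pair_frame(
            mk_pair("a", "chr1", 10_000, "+", "chr1", 60_000, "-"),
            mk_pair("b", "chr1", 10_000, "-", "chr1", 60_000, "+"))
        sigs = cluster_pairs(df, classify_pairs(df))
        assert len(sigs) == 2
        assert {s.sig_class.value for s in sigs} == {"DEL", "TD"}

    def test_distant_pairs_stay_apart(self):
        df = pair_frame(
            mk_pair("a", "chr1", 10_000, "+", "chr1", 60_000, "-"),
            mk_pair("b", "chr1", 20_000, "+", "chr1", 70_000, "-"))
        sigs = cluster_pairs(df, classify_pairs(df), join_distance=1_000)
        assert len(sigs) == 2 and all(s.support == 1 for s in sigs)

    def test_one_side_close_other_far_stays_apart(self):
        df = pair_frame(
            mk_pair("a", "chr1", 10_000, "+", "chr1", 60_000, "-"),
            mk_pair("b", "chr1", 10_200, "+", "chr1", 90_000, "-"))
        sigs = cluster_pairs(df, classify_pairs(df), join_distance=1_000)
        assert len(sigs) == 2

    def test_order_invariance(self):
        rng = np.random.default_rng(11)
        rows = []
        for i in range(60):
            base = int(rng.integers(0, 5)) * 50_000 + 10_000
            rows.append(mk_pair(f"p{i}", "chr1", base + int(rng.integers(0, 500)),
                                "+", "chr1",
                                base + 100_000 + int(rng.integers(0, 500)), "-"))
        df = pair_frame(*rows)
        perm = df.sample(frac=1, random_state=3).reset_index(drop=True)
        def key(sigs):
            return sorted((s.sig_class.value, s.intervalA, s.intervalB,
                           tuple(sorted(s.pair_ids))) for s in sigs)
        assert key(cluster_pairs(df, classify_pairs(df))) == \
            key(cluster_pairs(perm, classify_pairs(perm)))

    def test_concordant_rejected(self):
        df = pair_frame(mk_pair("a", "chr1", 10_000, "+", "chr1", 10_300, "-"))
        with pytest.raises(ValueError):
            cluster_pairs(df, classify_pairs(df))


class TestRefinedMap:
    def test_blacklist_removes_pair(self):
        df = pair_frame(mk_pair("a", "chr1", 10_000, "+", "chr1", 60_000, "-"))
        panel = FilterPanel(blacklist=merge_intervals(pd.DataFrame(
            {"chrom": ["chr1"], "start": [9_000], "end": [11_000]})))
        assert len(build_refined_map(df, panel)) == 0
        # and without the panel it is present
        assert len(build_refined_map(df)) == 1

    def test_alt_concordant_removed(self):
        df = pair_frame(
            mk_pair("a", "chr1", 10_000, "+", "chr1", 60_000, "-", alt=True))
        assert len(build_refined_map(df)) == 0

    def test_low_mapq_removed(self):
        df = pair_frame(
            mk_pair("a", "chr1", 10_000, "+", "chr1", 60_000, "-", mapq2=10))
        assert len(build_refined_map(df)) == 0

    def test_mitochondrial_removed(self):
        df = pair_frame(mk_pair("a", "chrM", 1_000, "+", "chr1", 60_000, "-"))
        panel = FilterPanel(mito_names={"chrM"})
        assert len(build_refined_map(df, panel)) == 0

    def test_germline_signature_removed(self):
        df = pair_frame(
            mk_pair("a", "chr1", 10_000, "+", "chr1", 60_000, "-"),
            mk_pair("b", "chr1", 10_200, "+", "chr1", 60_200, "-"),
            mk_pair("c", "chr1", 200_000, "+", "chr1", 280_000, "-"))
        germ = [RearrangementSignature(
            sig_class=SignatureClass.DEL, chromA="chr1",
            intervalA=(10_500, 10_900), chromB="chr1",
            intervalB=(60_500, 60_900), span=50_000, support=5)]
        m = build_refined_map(df, FilterPanel(germline=germ),
                              germline_tolerance=1_000)
        assert len(m) == 1
        assert m.signatures[0].intervalA[0] == 200_000

    def test_pair_conservation(self):
        rng = np.random.default_rng(21)
        rows = []
        for i in range(200):
            p1 = int(rng.integers(10_000, 5_000_000))
            span = int(rng.integers(10_000, 100_000))
            strands = [("+", "-"), ("-", "+"), ("+", "+")][int(rng.integers(3))]
            rows.append(mk_pair(f"p{i}", "chr1", p1, strands[0], "chr1",
                                p1 + span, strands[1]))
        df = pair_frame(*rows)
        m = build_refined_map(df)
        assert sum(s.support for s in m.signatures) == len(df)
        all_ids = [p for s in m.signatures for p in s.pair_ids]
        assert len(all_ids) == len(set(all_ids))  # no pair in two signatures


class TestThreshold:
    def _map(self):
        sigs = [
            RearrangementSignature(SignatureClass.DEL, "chr1", (0, 100), "chr1",
                                   (50_000, 50_100), 49_900, 1, ["a"]),
            RearrangementSignature(SignatureClass.DEL, "chr1", (0, 100), "chr1",
                                   (60_000, 60_100), 59_900, 2, ["b", "c"]),
            RearrangementSignature(SignatureClass.TD, "chr1", (0, 100), "chr1",
                                   (70_000, 70_100), 69_900, 8, list("defghijk")),
        ]
        from scpem.pairs import PairedEndMap
        return PairedEndMap(signatures=sigs)

    def test_support_threshold(self):
        assert len(threshold_map(self._map(), 2)) == 2
        assert len(threshold_map(self._map(), 20)) == 0

    def test_span_filter_with_itx_exemption(self):
        from scpem.pairs import ITX_SPAN, PairedEndMap
        sigs = [
            RearrangementSignature(SignatureClass.DEL, "chr1", (0, 10), "chr1",
                                   (3_000, 3_010), 2_990, 10, []),
            RearrangementSignature(SignatureClass.ITX, "chr1", (0, 10), "chr2",
                                   (3_000, 3_010), ITX_SPAN, 10, []),
        ]
        kept = threshold_map(PairedEndMap(signatures=sigs), 2, min_span=5_000)
        assert [s.sig_class.value for s in kept.signatures] == ["ITX"]

    def test_monotone_in_threshold(self):
        m = self._map()
        for t1, t2 in [(1, 2), (2, 5), (5, 9)]:
            ids1 = {id(s) for s in threshold_map(m, t1).signatures}
            ids2 = {id(s) for s in threshold_map(m, t2).signatures}
            assert ids2 <= ids1

    def test_reference_map_rule(self):
        m = self._map()
        assert [s.support for s in build_reference_map(m).signatures] == [2, 8]
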