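"""Integration of copy-number segments with paired-end maps.

Cross-checks between the two arms of the analysis: benchmarking a
single-cell refined paired-end map against a trusted reference map
(positive predictive value and sensitivity as a function of the
support-count threshold), using logR breakpoints as bait to fish
corroborating read-pair signatures out of the map, flagging false gains
caused by PCR pile-up artefacts, breakpoint/copy-number concordance
scoring, and reciprocal-event analysis of two sister cells separated by a
single division.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pairs import (ITX_SPAN, PairedEndMap, RearrangementSignature,
                    SignatureClass, threshold_map, _interval_distance)
from .pcf import Segment

DEFAULT_THRESHOLDS = range(2, 21)
DEFAULT_MATCH_TOLERANCE = 10_000
DEFAULT_BAIT_RADIUS = 50_000
DEFAULT_BREAKPOINT_DIST = 100_000


@dataclass
class MapMatch:
    query: RearrangementSignature
    reference: RearrangementSignature | None
    dist_a: int | None = None
    dist_b: int | None = None


def match_maps(query: list[RearrangementSignature],
               reference: list[RearrangementSignature],
               tolerance: int = DEFAULT_MATCH_TOLERANCE) -> list[MapMatch]:
    """Greedy one-to-one matching of query to reference signatures.

    A query may match a reference signature of the same class and
    chromosome pair whose per-side breakpoint-interval distances are both
    within ``tolerance``.  Candidate links are ranked by total distance
    (sum of the two sides) and assigned greedily, so no reference
    signature is used twice.
    """
    by_key: dict[tuple, list[int]] = {}
    for ri, r in enumerate(reference):
        by_key.setdefault((r.sig_class, r.chromA, r.chromB), []).append(ri)
    links = []
    for qi, q in enumerate(query):
        for ri in by_key.get((q.sig_class, q.chromA, q.chromB), ()):
            r = reference[ri]
            da = _interval_distance(q.intervalA, r.intervalA)
            db = _interval_distance(q.intervalB, r.intervalB)
            if da <= tolerance and db <= tolerance:
                links.append((da + db, qi, ri, da, db))
    links.sort(key=lambda t: (t[0], t[1], t[2]))
    matched_q: dict[int, tuple[int, int, int]] = {}
    used_r: set[int] = set()
    for total, qi, ri, da, db in links:
        if qi in matched_q or ri in used_r:
            continue
        matched_q[qi] = (ri, da, db)
        used_r.add(ri)
    out = []
    for qi, q in enumerate(query):
        if qi in matched_q:
            ri, da, db = matched_q[qi]
            out.append(MapMatch(q, reference[ri], da, db))
        else:
            out.append(MapMatch(q, None))
    return out


def _apply_span_filter(sigs: list[RearrangementSignature], min_span: int,
                       exempt_itx: bool = True) -> list[RearrangementSignature]:
    return [s for s in sigs
            if (exempt_itx and s.sig_class is SignatureClass.ITX) or s.span >= min_span]


def compute_ppv(query_map: PairedEndMap, reference_map: PairedEndMap,
                thresholds=DEFAULT_THRESHOLDS, min_span: int = 5_000,
                match_tolerance: int = DEFAULT_MATCH_TOLERANCE,
                itx_min_support: int | None = None) -> pd.DataFrame:
    """PPV per (threshold, class): matched / total surviving query signatures.

    The reference map is expected to be already reduced to its trusted
    form.  The span filter (ITX exempt) applies to the query at every
    threshold.  Cells with no surviving query signature hold NaN — PPV is
    undefined there, not zero.  ``itx_min_support`` optionally imposes a
    stricter class-specific support floor on inter-chromosomal signatures.
    """
    classes = [c.value for c in (SignatureClass.DEL, SignatureClass.TD,
                                 SignatureClass.INV, SignatureClass.ITX)]
    ref = reference_map.signatures
    rows = []
    for t in thresholds:
        surv = [s for s in threshold_map(query_map, t, min_span).signatures
                if not (itx_min_support and s.sig_class is SignatureClass.ITX
                        and s.support < itx_min_support)]
        matches = match_maps(surv, ref, match_tolerance)
        row = {"threshold": t}
        for cls in classes:
            cls_m = [m for m in matches if m.query.sig_class.value == cls]
            row[cls] = (sum(m.reference is not None for m in cls_m) / len(cls_m)
                        if cls_m else np.nan)
        rows.append(row)
    return pd.DataFrame(rows).set_index("threshold")


def compute_sensitivity(query_map: PairedEndMap,
                        validated_set: list[RearrangementSignature],
                        thresholds=DEFAULT_THRESHOLDS,
                        match_tolerance: int = DEFAULT_MATCH_TOLERANCE) -> pd.Series:
    """Fraction of a validated signature set recovered at each threshold.

    A validated signature is recovered at threshold t when the query map
    holds a matching signature (same class/chromosomes, both sides within
    tolerance) with support >= t.
    """
    if not validated_set:
        raise ValueError("validated set is empty")
    out = {}
    for t in thresholds:
        surv = [s for s in query_map.signatures if s.support >= t]
        matches = match_maps(validated_set, surv, match_tolerance)
        out[t] = sum(m.reference is not None for m in matches) / len(validated_set)
    return pd.Series(out, name="sensitivity").rename_axis("threshold")


def bait_capture(refined_map: PairedEndMap,
                 logr_breakpoints: dict[str, np.ndarray],
                 radius: int = DEFAULT_BAIT_RADIUS) -> list[dict]:
    """Fish signatures out of the refined map around logR breakpoints.

    ``logr_breakpoints`` maps chromosome to an (n, 2) array of
    (position, logR step) rows, as produced by
    :func:`scpem.pcf.segment_breakpoints`.  A signature is captured when
    at least one of its breakpoint intervals intersects
    [pos - radius, pos + radius] of some logR breakpoint.  The
    ``consistent`` flag records whether the signature class agrees with
    the sign of the logR step at the capturing breakpoint (DEL with a
    drop, TD with a rise); inversions and inter-chromosomal signatures
    carry no expected sign and report None.
    """
    captured = []
    for sig in refined_map.signatures:
        best = None
        for chrom, interval in ((sig.chromA, sig.intervalA),
                                (sig.chromB, sig.intervalB)):
            bps = logr_breakpoints.get(chrom)
            if bps is None or len(bps) == 0:
                continue
            for pos, step in bps:
                d = _interval_distance(interval, (int(pos) - radius, int(pos) + radius))
                if d == 0:
                    gap = _interval_distance(interval, (int(pos), int(pos)))
                    if best is None or gap < best[0]:
                        best = (gap, float(step))
        if best is None:
            continue
        _, step = best
        if sig.sig_class is SignatureClass.DEL:
            consistent = step < 0
        elif sig.sig_class is SignatureClass.TD:
            consistent = step > 0
        else:
            consistent = None
        captured.append({"signature": sig, "logr_step": step,
                         "consistent": consistent})
    return captured


def flag_pcr_pileup_gains(gain_segments: list[Segment],
                          refined_map: PairedEndMap,
                          tiny_span: int = 5_000, min_tiny_td: int = 2,
                          flank: int = 50_000) -> list[dict]:
    """Flag gains that look like PCR pile-up artefacts.

    PCR-based WGA can pile reads onto a locus, creating an apparent gain
    whose only read-pair evidence is a cloud of tiny flanking tandem
    duplications.  A gain segment is flagged as an artefact when at least
    ``min_tiny_td`` TD signatures of span below ``tiny_span`` lie within
    the segment extended by ``flank`` on each side, and no signature of
    span at least the segment length corroborates the gain.
    """
    out = []
    for seg in gain_segments:
        lo, hi = seg.start_bp - flank, seg.end_bp + flank
        seg_len = seg.end_bp - seg.start_bp
        tiny = 0
        corroborated = False
        for sig in refined_map.signatures:
            near = ((sig.chromA == seg.chrom
                     and _interval_distance(sig.intervalA, (lo, hi)) == 0)
                    or (sig.chromB == seg.chrom
                        and _interval_distance(sig.intervalB, (lo, hi)) == 0))
            if not near:
                continue
            if sig.sig_class is SignatureClass.TD and 0 <= sig.span < tiny_span:
                tiny += 1
            if sig.span >= seg_len and sig.span != ITX_SPAN:
                corroborated = True
        flagged = tiny >= min_tiny_td and not corroborated
        out.append({"segment": seg, "n_tiny_td": tiny,
                    "corroborated": corroborated, "artefact": flagged})
    return out


def breakpoint_cn_concordance(cell_segments: list[Segment],
                              reference_events: list[dict],
                              max_dist: int = DEFAULT_BREAKPOINT_DIST) -> float:
    """Fraction of reference CN events matched by the cell's segmentation.

    Each reference event carries ``chrom``, ``pos`` (breakpoint) and
    ``cn``.  It matches when the cell has a segment of identical integer
    CN whose nearer boundary lies within ``max_dist`` of the event
    breakpoint.
    """
    if not reference_events:
        raise ValueError("empty reference event set")
    matched = 0
    for ev in reference_events:
        for seg in cell_segments:
            if seg.chrom != ev["chrom"] or seg.cn != ev["cn"]:
                continue
            near = min(abs(seg.start_bp - ev["pos"]), abs(seg.end_bp - ev["pos"]))
            if near <= max_dist:
                matched += 1
                break
    return matched / len(reference_events)


def cn_concordance(cell_cn: np.ndarray, reference_cn: np.ndarray,
                   mask: np.ndarray | None = None) -> float:
    """Fraction of shared bins with identical integer copy number."""
    cell_cn = np.asarray(cell_cn)
    reference_cn = np.asarray(reference_cn)
    if mask is not None:
        cell_cn = cell_cn[mask]
        reference_cn = reference_cn[mask]
    if len(cell_cn) == 0:
        raise ValueError("no bins in common")
    if len(cell_cn) != len(reference_cn):
        raise ValueError("profiles are on different grids")
    return float(np.mean(cell_cn == reference_cn))


@dataclass
class ReciprocalEvent:
    chrom: str
    start: int
    end: int
    cn_cell_a: int
    cn_cell_b: int
    cn_consensus: int
    kind: str  # reciprocal | unbalanced_gain | unbalanced_loss


def _deviant_runs(segs: list[Segment], consensus,
                  boundary_tol: int = 100_000) -> list[tuple[str, int, int, int, int]]:
    """Maximal runs of segments deviating from consensus CN.

    Returns (chrom, start, end, cn, consensus_cn) tuples.  Adjacent
    deviant segments whose deviations share a sign are merged when
    separated by at most ``boundary_tol`` (segmentation of a single event
    may fragment it, or leave small gaps over dropped bins); the merged
    run reports the CN of its longest constituent.
    """
    runs: list[list] = []  # [chrom, start, end, cn, cons, longest_piece]
    called_since: dict[str, int] = {}  # consensus-CN bp since the last run
    for seg in sorted(segs, key=lambda s: (s.chrom, s.start_bp)):
        cons = consensus(seg.chrom, seg.start_bp, seg.end_bp)
        if seg.cn is None or seg.cn == cons:
            called_since[seg.chrom] = (called_since.get(seg.chrom, 0)
                                       + seg.end_bp - seg.start_bp)
            continue
        size = seg.end_bp - seg.start_bp
        if (runs and runs[-1][0] == seg.chrom
                and (seg.cn - cons) * (runs[-1][3] - runs[-1][4]) > 0
                and called_since.get(seg.chrom, 0) <= boundary_tol):
            # fragments of one event: separated only by dropped-bin holes
            # or by sub-tolerance stretches called at the consensus
            last = runs[-1]
            last[2] = seg.end_bp
            if size > last[5]:
                last[3], last[4], last[5] = seg.cn, cons, size
        else:
            runs.append([seg.chrom, seg.start_bp, seg.end_bp, seg.cn, cons, size])
        called_since[seg.chrom] = 0
    return [(c, s, e, cn, cons) for c, s, e, cn, cons, _ in runs]


def reciprocal_events(segments_a: list[Segment], segments_b: list[Segment],
                      consensus, min_overlap: float = 0.5,
                      boundary_tol: int = 100_000) -> list[ReciprocalEvent]:
    """Classify CN deviations of two sister cells against a consensus.

    ``consensus`` is a callable (chrom, start, end) -> integer CN — the
    subclone/truth profile both daughters are compared against.  Regions
    where the two cells deviate with opposite signs and reciprocal overlap
    of at least ``min_overlap`` are *reciprocal* events (the hallmark of a
    mis-segregation in the preceding division); a deviation seen in one
    cell only is an unbalanced gain or loss.
    """
    runs_a = _deviant_runs(segments_a, consensus, boundary_tol)
    runs_b = _deviant_runs(segments_b, consensus, boundary_tol)
    events: list[ReciprocalEvent] = []
    used_b: set[int] = set()
    for ca, sa, ea, cna, consa in runs_a:
        hit = None
        for bi, (cb, sb, eb, cnb, consb) in enumerate(runs_b):
            if bi in used_b or cb != ca:
                continue
            ov = min(ea, eb) - max(sa, sb)
            if ov <= 0:
                continue
            if ov / (ea - sa) < min_overlap or ov / (eb - sb) < min_overlap:
                continue
            if (cna - consa) * (cnb - consb) < 0:
                hit = bi
                break
        if hit is not None:
            cb, sb, eb, cnb, consb = runs_b[hit]
            used_b.add(hit)
            events.append(ReciprocalEvent(ca, max(sa, sb), min(ea, eb),
                                          cna, cnb, consa, "reciprocal"))
        else:
            kind = "unbalanced_gain" if cna > consa else "unbalanced_loss"
            cn_b = consensus(ca, sa, ea)  # B agrees with consensus here
            events.append(ReciprocalEvent(ca, sa, ea, cna, cn_b, consa, kind))
    for bi, (cb, sb, eb, cnb, consb) in enumerate(runs_b):
        if bi in used_b:
            continue
        kind = "unbalanced_gain" if cnb > consb else "unbalanced_loss"
        events.append(ReciprocalEvent(cb, sb, eb, consb, cnb, consb, kind))
    return events


def events_frame(events: list[ReciprocalEvent]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": e.chrom, "start": e.start, "end": e.end, "kind": e.kind,
        "cn_cell_a": e.cn_cell_a, "cn_cell_b": e.cn_cell_b,
        "cn_consensus": e.cn_consensus,
    } for e in events])
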