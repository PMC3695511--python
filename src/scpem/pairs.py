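"""Discordant read-pair analysis: classification, clustering, filtering.

A paired-end library sequenced from a single-cell WGA product contains,
besides concordant fragments, read pairs whose mapped geometry contradicts
the expected insert: those are evidence for structural rearrangement — or,
far more often in WGA material, for chimeric amplification artefacts.
This module turns a table of discordant pairs into a *refined paired-end
map*: pairs are filtered against pile-up/repeat/mitochondrial panels and
known germline variation, classified into four signature classes by mapped
orientation, and single-linkage clustered into rearrangement signatures
whose support count (number of clustered pairs) drives downstream
thresholding.

Orientation conventions (standard Illumina FR geometry, records stored
with the lower coordinate first):

========  =======================  =================================
class     strand pattern           geometry
========  =======================  =================================
DEL       (+, -) span > insert     deletion: mates too far apart
TD        (-, +) everted           tandem duplication
INV       (+, +) or (-, -)         inversion: mates on one strand
ITX       different chromosomes    inter-chromosomal rearrangement
========  =======================  =================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

PAIR_COLUMNS = ["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2",
                "mapq1", "mapq2", "alt_concordant", "pair_id"]

DEFAULT_INSERT_MIN = 200
DEFAULT_INSERT_MAX = 500
DEFAULT_JOIN_DISTANCE = 1_000
DEFAULT_MAPQ_MIN = 30
DEFAULT_GERMLINE_TOLERANCE = 1_000
DEFAULT_MIN_SPAN = 5_000
ITX_SPAN = -1  # inter-chromosomal signatures have no defined span


class SignatureClass(str, Enum):
    DEL = "DEL"
    TD = "TD"
    INV = "INV"
    ITX = "ITX"
    CONCORDANT = "CONCORDANT"


@dataclass
class RearrangementSignature:
    sig_class: SignatureClass
    chromA: str
    intervalA: tuple[int, int]   # min-max of clustered left-end positions
    chromB: str
    intervalB: tuple[int, int]
    span: int                    # ITX_SPAN for inter-chromosomal
    support: int
    pair_ids: list = field(default_factory=list)


@dataclass
class FilterPanel:
    """Interval panels a refined map is filtered against.

    ``blacklist``/``repeats`` map chromosome to a merged, sorted
    (starts, ends) pair of arrays; ``mito_names`` is a set of chromosome
    names; ``germline`` is a reference signature list whose matches are
    removed as inherited variation.
    """

    blacklist: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    repeats: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    mito_names: set[str] = field(default_factory=set)
    germline: list[RearrangementSignature] = field(default_factory=list)


@dataclass
class PairedEndMap:
    signatures: list[RearrangementSignature]
    filters_applied: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.signatures)

    def counts_by_class(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for sig in self.signatures:
            out[sig.sig_class.value] = out.get(sig.sig_class.value, 0) + 1
        return out


def merge_intervals(intervals: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Merge a BED-like (chrom,start,end) table into sorted disjoint arrays."""
    out = {}
    for chrom, grp in intervals.groupby("chrom", sort=False):
        arr = grp[["start", "end"]].to_numpy(dtype=np.int64)
        arr = arr[np.argsort(arr[:, 0], kind="stable")]
        starts, ends = [], []
        for s, e in arr:
            if ends and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        out[str(chrom)] = (np.array(starts, np.int64), np.array(ends, np.int64))
    return out


def _in_intervals(chroms: np.ndarray, pos: np.ndarray,
                  panel: dict[str, tuple[np.ndarray, np.ndarray]]) -> np.ndarray:
    """Vectorised point-in-merged-intervals test."""
    hit = np.zeros(len(pos), dtype=bool)
    if not panel:
        return hit
    for chrom, (starts, ends) in panel.items():
        sel = chroms == chrom
        if not sel.any() or len(starts) == 0:
            continue
        idx = np.searchsorted(starts, pos[sel], side="right") - 1
        ok = idx >= 0
        inside = np.zeros(sel.sum(), dtype=bool)
        inside[ok] = pos[sel][ok] < ends[idx[ok]]
        hit[sel] = inside
    return hit


def classify_pairs(pairs: pd.DataFrame, insert_min: int = DEFAULT_INSERT_MIN,
                   insert_max: int = DEFAULT_INSERT_MAX) -> np.ndarray:
    """Vectorised signature class per pair (array of class-name strings).

    Pairs must be in canonical order ((chrom1,pos1) <= (chrom2,pos2)).
    Short-insert (+,-) pairs are treated as concordant: small insertions
    are not modelled.
    """
    s1 = pairs["strand1"].to_numpy()
    s2 = pairs["strand2"].to_numpy()
    if not np.all(np.isin(s1, ["+", "-"])) or not np.all(np.isin(s2, ["+", "-"])):
        raise ValueError("strands must be '+' or '-'")
    inter = (pairs["chrom1"] != pairs["chrom2"]).to_numpy()
    span = (pairs["pos2"] - pairs["pos1"]).to_numpy()
    out = np.full(len(pairs), SignatureClass.CONCORDANT.value, dtype=object)
    out[inter] = SignatureClass.ITX.value
    intra = ~inter
    fr = intra & (s1 == "+") & (s2 == "-")
    out[fr & (span > insert_max)] = SignatureClass.DEL.value
    out[intra & (s1 == "-") & (s2 == "+")] = SignatureClass.TD.value
    out[intra & (s1 == s2)] = SignatureClass.INV.value
    return out.astype(str)


def classify_pair(pair: pd.Series | dict, insert_min: int = DEFAULT_INSERT_MIN,
                  insert_max: int = DEFAULT_INSERT_MAX) -> SignatureClass:
    """Single-record convenience wrapper around :func:`classify_pairs`."""
    df = pd.DataFrame([dict(pair)])
    return SignatureClass(classify_pairs(df, insert_min, insert_max)[0])


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self, n: int):
        self.parent = np.arange(n, dtype=np.int64)

    def find(self, i: int) -> int:
        p = self.parent
        root = i
        while p[root] != root:
            root = p[root]
        while p[i] != root:  # path compression
            p[i], i = root, p[i]
        return root

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_pairs(pairs: pd.DataFrame, classes: np.ndarray,
                  join_distance: int = DEFAULT_JOIN_DISTANCE) -> list[RearrangementSignature]:
    """Single-linkage clustering of classified discordant pairs.

    Two pairs join iff they share the signature class, strand pattern and
    chromosome pair, and both their pos1 and pos2 coordinates differ by at
    most ``join_distance``.  Signature intervals are the min-max of member
    positions; support is the cluster size.  Concordant pairs must be
    excluded beforehand.
    """
    if np.any(classes == SignatureClass.CONCORDANT.value):
        raise ValueError("exclude CONCORDANT pairs before clustering")
    sigs: list[RearrangementSignature] = []
    keys = pd.DataFrame({
        "cls": classes,
        "c1": pairs["chrom1"].to_numpy(),
        "c2": pairs["chrom2"].to_numpy(),
        "sp": pairs["strand1"].astype(str).to_numpy() +
              pairs["strand2"].astype(str).to_numpy(),
    }, index=pairs.index)
    for (cls, _c1, _c2, _sp), grp in keys.groupby(["cls", "c1", "c2", "sp"], sort=False):
        sub = pairs.loc[grp.index]
        order = np.argsort(sub["pos1"].to_numpy(), kind="stable")
        p1 = sub["pos1"].to_numpy()[order]
        p2 = sub["pos2"].to_numpy()[order]
        ids = sub["pair_id"].to_numpy()[order]
        n = len(p1)
        uf = _UnionFind(n)
        left = np.searchsorted(p1, p1 - join_distance, side="left")
        k = 1
        while True:
            i = np.arange(k, n)
            valid = i - k >= left[k:]
            if not valid.any():
                break
            i = i[valid]
            close2 = np.abs(p2[i] - p2[i - k]) <= join_distance
            for a in i[close2]:
                uf.union(int(a), int(a - k))
            k += 1
        roots = np.array([uf.find(i) for i in range(n)])
        for root in np.unique(roots):
            m = roots == root
            a_lo, a_hi = int(p1[m].min()), int(p1[m].max())
            b_lo, b_hi = int(p2[m].min()), int(p2[m].max())
            cls_e = SignatureClass(cls)
            if cls_e is SignatureClass.ITX:
                span = ITX_SPAN
            else:
                # distance between inner breakpoint estimates
                span = max(0, b_lo - a_hi)
            sigs.append(RearrangementSignature(
                sig_class=cls_e,
                chromA=str(sub["chrom1"].iloc[0]), intervalA=(a_lo, a_hi),
                chromB=str(sub["chrom2"].iloc[0]), intervalB=(b_lo, b_hi),
                span=span, support=int(m.sum()),
                pair_ids=list(ids[m]),
            ))
    return sigs


def build_refined_map(pairs: pd.DataFrame, panel: FilterPanel | None = None,
                      insert_min: int = DEFAULT_INSERT_MIN,
                      insert_max: int = DEFAULT_INSERT_MAX,
                      join_distance: int = DEFAULT_JOIN_DISTANCE,
                      mapq_min: int = DEFAULT_MAPQ_MIN,
                      germline_tolerance: int = DEFAULT_GERMLINE_TOLERANCE) -> PairedEndMap:
    """Filter, classify and cluster discordant pairs into a refined map.

    Pairs are dropped when either end overlaps the pile-up blacklist or
    repeat panel, either chromosome is mitochondrial, the pair has a
    concordant alternative alignment, or min(mapq1, mapq2) < ``mapq_min``.
    After clustering, signatures matching the germline reference map
    (same class, both breakpoint intervals within ``germline_tolerance``)
    are removed.
    """
    panel = panel or FilterPanel()
    n0 = len(pairs)
    c1 = pairs["chrom1"].to_numpy().astype(str)
    c2 = pairs["chrom2"].to_numpy().astype(str)
    p1 = pairs["pos1"].to_numpy()
    p2 = pairs["pos2"].to_numpy()
    drop = np.zeros(n0, dtype=bool)
    for pan in (panel.blacklist, panel.repeats):
        drop |= _in_intervals(c1, p1, pan) | _in_intervals(c2, p2, pan)
    if panel.mito_names:
        drop |= np.isin(c1, list(panel.mito_names)) | np.isin(c2, list(panel.mito_names))
    drop |= pairs["alt_concordant"].to_numpy().astype(bool)
    drop |= np.minimum(pairs["mapq1"].to_numpy(), pairs["mapq2"].to_numpy()) < mapq_min
    kept = pairs.loc[~drop]
    classes = classify_pairs(kept, insert_min, insert_max)
    disc = classes != SignatureClass.CONCORDANT.value
    sigs = cluster_pairs(kept.loc[disc], classes[disc], join_distance)
    n_before_germline = len(sigs)
    if panel.germline:
        sigs = [s for s in sigs
                if not _matches_germline(s, panel.germline, germline_tolerance)]
    return PairedEndMap(
        signatures=sigs,
        filters_applied={
            "input_pairs": int(n0),
            "dropped_by_panels": int(drop.sum()),
            "concordant": int((~disc).sum()),
            "germline_removed": n_before_germline - len(sigs),
        },
        params={"insert_min": insert_min, "insert_max": insert_max,
                "join_distance": join_distance, "mapq_min": mapq_min,
                "germline_tolerance": germline_tolerance},
    )


def _interval_distance(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Gap between two intervals; 0 when they overlap or touch."""
    return max(0, max(a[0], b[0]) - min(a[1], b[1]))


def _matches_germline(sig: RearrangementSignature,
                      germline: list[RearrangementSignature], tol: int) -> bool:
    for g in germline:
        if (g.sig_class == sig.sig_class and g.chromA == sig.chromA
                and g.chromB == sig.chromB
                and _interval_distance(sig.intervalA, g.intervalA) <= tol
                and _interval_distance(sig.intervalB, g.intervalB) <= tol):
            return True
    return False


def threshold_map(pemap: PairedEndMap, min_support: int,
                  min_span: int = DEFAULT_MIN_SPAN,
                  exempt_itx: bool = True) -> PairedEndMap:
    """Keep signatures with enough support and span.

    A signature survives iff its support is at least ``min_support`` and
    its span is at least ``min_span``; inter-chromosomal signatures have
    no span and are exempt from the span rule when ``exempt_itx``.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    kept = [s for s in pemap.signatures
            if s.support >= min_support
            and ((exempt_itx and s.sig_class is SignatureClass.ITX)
                 or s.span >= min_span)]
    return PairedEndMap(signatures=kept,
                        filters_applied=dict(pemap.filters_applied),
                        params={**pemap.params, "min_support": min_support,
                                "min_span": min_span, "exempt_itx": exempt_itx})


def build_reference_map(pemap: PairedEndMap) -> PairedEndMap:
    """The reference-map reduction: >= 2 supporting pairs and >= 5 kb span
    (span rule waived for inter-chromosomal signatures)."""
    return threshold_map(pemap, min_support=2, min_span=DEFAULT_MIN_SPAN,
                         exempt_itx=True)


def pileup_blacklist_from_reference(bins: pd.DataFrame,
                                    n_sd: float = 5.0) -> pd.DataFrame:
    """Helper: derive a pile-up blacklist from reference-sample bin depth.

    Bins whose reference count exceeds mean + ``n_sd`` standard deviations
    are emitted as blacklist intervals (BED-like frame).  Users with a
    curated pile-up BED should supply that instead.
    """
    counts = bins["count_ref"].to_numpy(dtype=float)
    cut = counts.mean() + n_sd * counts.std()
    hot = bins.loc[counts > cut, ["chrom", "start", "end"]]
    return hot.reset_index(drop=True)


def map_frame(pemap: PairedEndMap) -> pd.DataFrame:
    """Signatures as a BEDPE-like table."""
    return pd.DataFrame([{
        "chromA": s.chromA, "startA": s.intervalA[0], "endA": s.intervalA[1] + 1,
        "chromB": s.chromB, "startB": s.intervalB[0], "endB": s.intervalB[1] + 1,
        "name": s.sig_class.value, "score": s.support, "span": s.span,
        "pair_ids": ";".join(str(p) for p in s.pair_ids),
    } for s in pemap.signatures])
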