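"""Table readers and writers, bin counting and alignment ingestion.

All tables are tab-separated UTF-8 text with a single ``#``-prefixed
header line.  BED and BEDPE outputs use standard 0-based half-open
coordinates.  Every writer here has a matching reader that round-trips
its output exactly.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .cnv import BIN_COLUMNS
from .pairs import (PAIR_COLUMNS, FilterPanel, PairedEndMap,
                    RearrangementSignature, SignatureClass, map_frame,
                    merge_intervals)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """TSV with a '#'-prefixed header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#"):
            raise ValueError(f"{path}: expected a '#'-prefixed header line")
        names = header[1:].split("\t")
        return pd.read_csv(fh, sep="\t", names=names)


def write_bins(bins: pd.DataFrame, path: str | Path) -> None:
    write_table(bins[BIN_COLUMNS], path)


def read_bins(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    missing = set(BIN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing bin columns {sorted(missing)}")
    return df[BIN_COLUMNS]


def write_pairs(pairs: pd.DataFrame, path: str | Path) -> None:
    out = pairs[PAIR_COLUMNS].copy()
    out["alt_concordant"] = out["alt_concordant"].astype(int)
    write_table(out, path)


def read_pairs(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    df["alt_concordant"] = df["alt_concordant"].astype(bool)
    return df[PAIR_COLUMNS]


def write_segments(segments_df: pd.DataFrame, path: str | Path) -> None:
    """BED3 + mean_logr, n_bins, cn."""
    write_table(segments_df[["chrom", "start", "end", "mean_logr", "n_bins", "cn"]],
                path)


def read_segments(path: str | Path) -> pd.DataFrame:
    return read_table(path)


def write_map(pemap: PairedEndMap, path: str | Path) -> None:
    write_table(map_frame(pemap), path)


def read_map(path: str | Path) -> PairedEndMap:
    df = read_table(path)
    sigs = []
    for _, r in df.iterrows():
        raw = r["pair_ids"]
        ids = [] if pd.isna(raw) or raw == "" else str(raw).split(";")
        sigs.append(RearrangementSignature(
            sig_class=SignatureClass(r["name"]),
            chromA=str(r["chromA"]), intervalA=(int(r["startA"]), int(r["endA"]) - 1),
            chromB=str(r["chromB"]), intervalB=(int(r["startB"]), int(r["endB"]) - 1),
            span=int(r["span"]), support=int(r["score"]), pair_ids=ids))
    return PairedEndMap(signatures=sigs)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Plain BED3 (no header, '#' comment lines allowed)."""
    return pd.read_csv(path, sep="\t", comment="#", header=None,
                       usecols=[0, 1, 2], names=["chrom", "start", "end"],
                       dtype={"chrom": str})


def read_germline_bedpe(path: str | Path) -> list[RearrangementSignature]:
    """BEDPE with a 7th column naming the signature class."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chromA", "startA", "endA", "chromB", "startB",
                            "endB", "name"], dtype={"chromA": str, "chromB": str})
    return [RearrangementSignature(
        sig_class=SignatureClass(r["name"]), chromA=r["chromA"],
        intervalA=(int(r["startA"]), int(r["endA"]) - 1), chromB=r["chromB"],
        intervalB=(int(r["startB"]), int(r["endB"]) - 1), span=0, support=2)
        for _, r in df.iterrows()]


def load_panel(blacklist: str | Path | None = None,
               repeats: str | Path | None = None,
               mito_names: str | Path | None = None,
               germline: str | Path | None = None) -> FilterPanel:
    """Assemble a filter panel from files; absent components are empty."""
    panel = FilterPanel()
    for attr, path in (("blacklist", blacklist), ("repeats", repeats)):
        if path is None:
            warnings.warn(f"no {attr} panel supplied; treating as empty",
                          stacklevel=2)
            continue
        setattr(panel, attr, merge_intervals(read_bed(path)))
    if mito_names is not None:
        panel.mito_names = {line.strip() for line in open(mito_names)
                            if line.strip()}
    if germline is not None:
        panel.germline = read_germline_bedpe(germline)
    return panel


def write_truth_manifest(truth, outdir: str | Path) -> None:
    """Truth genome as scoring files: segments BED+, SVs BEDPE, genotypes TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seg = truth.segments.copy()
    seg["cn"] = seg["cn_a"] + seg["cn_b"]
    write_table(seg[["chrom", "start", "end", "cn_a", "cn_b", "cn"]],
                outdir / "truth_segments.bed")
    sv = truth.svs.copy()
    if len(sv):
        write_table(sv[["chrom1", "pos1", "chrom2", "pos2", "sig_class", "span",
                        "cn_change"]], outdir / "truth_svs.bedpe")
    write_table(truth.snps, outdir / "truth_genotypes.tsv")
    with open(outdir / "truth_meta.json", "w") as fh:
        json.dump({"chrom_lengths": truth.chrom_lengths, "psi": truth.psi,
                   "background_cn": truth.background_cn}, fh, indent=1)


def write_provenance(path: str | Path, params: dict,
                     inputs: dict[str, str | Path] | None = None) -> None:
    """Record package version, parameters and input digests for a run."""
    import hashlib

    from . import __version__

    digests = {}
    for name, p in (inputs or {}).items():
        h = hashlib.sha256()
        with open(p, "rb") as fh:
            for chunk in iter(lambda: fh.read(65536), b""):
                h.update(chunk)
        digests[name] = h.hexdigest()
    payload = {"package": "scpem", "version": __version__,
               "params": params, "input_sha256": digests}
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=str)


# ---------------------------------------------------------------------------
# Position counting and alignment-file ingestion

def count_positions_into_bins(positions: pd.DataFrame, bins: pd.DataFrame,
                              min_mapq: int = 30) -> np.ndarray:
    """Count mapped-read positions into (possibly overlapping) sliding bins.

    ``positions`` columns: chrom, pos, mapq.  Each position with mapping
    quality >= ``min_mapq`` increments every bin that covers it.
    Positions on chromosomes absent from the bin grid are skipped (one
    summary warning).
    """
    counts = np.zeros(len(bins), dtype=np.int64)
    qual = positions.loc[positions["mapq"] >= min_mapq]
    skipped = 0
    bin_chroms = bins["chrom"].to_numpy()
    for chrom, grp in qual.groupby("chrom", sort=False):
        sel = np.flatnonzero(bin_chroms == str(chrom))
        if len(sel) == 0:
            skipped += len(grp)
            continue
        starts = bins["start"].to_numpy()[sel]
        window = int((bins["end"] - bins["start"]).to_numpy()[sel].max())
        pos = grp["pos"].to_numpy()
        lo = np.searchsorted(starts, pos - window, side="right")
        hi = np.searchsorted(starts, pos, side="right")
        delta = np.zeros(len(sel) + 1, dtype=np.int64)
        np.add.at(delta, lo, 1)
        np.add.at(delta, hi, -1)
        local = np.cumsum(delta[:-1])
        # guard against truncated bins that end before the position
        ends = bins["end"].to_numpy()[sel]
        # positions beyond a bin's end cannot be inside it: only possible for
        # the last (truncated) bins; correct by explicit check there
        short = np.flatnonzero(ends - starts < window)
        for i in short:
            inside = (pos >= starts[i]) & (pos < ends[i])
            local[i] = int(inside.sum())
        counts[sel] += local
    if skipped:
        warnings.warn(f"{skipped} positions on chromosomes absent from the "
                      f"bin grid were skipped", stacklevel=2)
    return counts


def positions_from_alignments(path: str | Path) -> pd.DataFrame:
    """(chrom, pos, mapq) of primary mapped reads in a SAM/BAM/CRAM file."""
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            rows.append((read.reference_name, read.reference_start,
                         read.mapping_quality))
    return pd.DataFrame(rows, columns=["chrom", "pos", "mapq"])


def pairs_from_alignments(path: str | Path) -> pd.DataFrame:
    """Discordant read pairs from an alignment file, in the pair-table dialect.

    Primary alignments flagged paired and not proper are collected; each
    pair is reported once, in canonical (lower coordinate first) order.
    Strand is '-' for reverse-complement alignments.  The
    ``alt_concordant`` column is 0 throughout — evaluating alternative
    alignments requires the aligner's auxiliary tags and is left to
    dedicated upstream tooling.
    """
    import pysam

    from .simulate import _canonicalize

    seen: dict[str, tuple] = {}
    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for read in fh:
            if (read.is_unmapped or read.mate_is_unmapped or read.is_secondary
                    or read.is_supplementary or not read.is_paired
                    or read.is_proper_pair):
                continue
            key = read.query_name
            this = (read.reference_name, read.reference_start,
                    "-" if read.is_reverse else "+", read.mapping_quality)
            if key in seen:
                other = seen.pop(key)
                rows.append({
                    "chrom1": other[0], "pos1": other[1], "strand1": other[2],
                    "chrom2": this[0], "pos2": this[1], "strand2": this[2],
                    "mapq1": other[3], "mapq2": this[3],
                    "alt_concordant": False, "pair_id": key,
                })
            else:
                seen[key] = this
    df = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    if len(df):
        df = _canonicalize(df).reset_index(drop=True)
    return df
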