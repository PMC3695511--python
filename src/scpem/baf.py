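"""Digital B-allele fractions, genotype calls, LOH support and
nucleotide-mismatch profiling.

The WGA product of a single cell can be genotyped digitally: for each
known SNP the reads spanning it are split into A- and B-allele counts,
and the B-allele fraction (BAF) is simply b / (a + b).  Over a deleted
(CN 1) region the surviving haplotype forces informative SNPs to extreme
BAF — loss of heterozygosity — which corroborates a depth-based deletion
call.  Per-read-cycle mismatch frequencies characterise the nucleotide
copy fidelity of the amplification chemistry; two chemistries are
compared with a two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

SNP_COLUMNS = ["chrom", "pos", "ref_allele", "alt_allele", "a_reads", "b_reads"]

DEFAULT_MIN_DEPTH = 2
DEFAULT_HOM_MAX_BAF = 0.1


@dataclass
class MismatchProfile:
    """Per-read-cycle mismatch frequency with its denominators."""

    frequency: np.ndarray   # mismatches / qualifying bases, per cycle
    mismatches: np.ndarray
    bases: np.ndarray

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cycle": np.arange(len(self.frequency)),
            "mismatches": self.mismatches,
            "bases": self.bases,
            "frequency": self.frequency,
        })


def compute_baf(snps: pd.DataFrame) -> pd.DataFrame:
    """Add ``depth`` and ``baf`` columns; BAF is NaN where depth is zero."""
    out = snps.copy()
    a = out["a_reads"].to_numpy(dtype=float)
    b = out["b_reads"].to_numpy(dtype=float)
    depth = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        baf = np.where(depth > 0, b / depth, np.nan)
    out["depth"] = depth.astype(np.int64)
    out["baf"] = baf
    return out


def call_genotypes(snps: pd.DataFrame, min_depth: int = DEFAULT_MIN_DEPTH,
                   hom_max_baf: float = DEFAULT_HOM_MAX_BAF) -> pd.Series:
    """Digital genotype per SNP: AA / AB / BB / NOCALL.

    NOCALL below ``min_depth``; AA when BAF <= ``hom_max_baf`` (boundary
    inclusive), BB when BAF >= 1 - ``hom_max_baf``, AB in between.
    """
    with_baf = compute_baf(snps)
    depth = with_baf["depth"].to_numpy()
    baf = with_baf["baf"].to_numpy()
    out = np.full(len(snps), "AB", dtype=object)
    out[baf <= hom_max_baf] = "AA"
    out[baf >= 1 - hom_max_baf] = "BB"
    out[depth < min_depth] = "NOCALL"
    return pd.Series(out, index=snps.index, name="genotype")


def loh_support(baf_records: pd.DataFrame, segment: tuple[str, int, int],
                informative: pd.DataFrame | np.ndarray,
                min_depth: int = 10, extreme: float = 0.1) -> float | None:
    """Fraction of informative SNPs in a segment showing extreme BAF.

    ``informative`` marks SNPs known heterozygous in a matched multi-cell
    or truth genotype (boolean mask aligned with ``baf_records``, or a
    (chrom, pos) frame).  Only informative SNPs inside the segment with
    depth >= ``min_depth`` are scored; extreme means BAF <= ``extreme``
    or >= 1 - ``extreme``.  Returns None when no SNP qualifies.
    """
    rec = compute_baf(baf_records) if "baf" not in baf_records else baf_records
    if isinstance(informative, pd.DataFrame):
        key = set(zip(informative["chrom"], informative["pos"]))
        mask = np.array([(c, p) in key for c, p in zip(rec["chrom"], rec["pos"])])
    else:
        mask = np.asarray(informative, dtype=bool)
    chrom, lo, hi = segment
    inside = ((rec["chrom"] == chrom) & (rec["pos"] >= lo)
              & (rec["pos"] < hi)).to_numpy()
    sel = mask & inside & (rec["depth"].to_numpy() >= min_depth)
    if sel.sum() == 0:
        return None
    baf = rec.loc[sel, "baf"].to_numpy()
    return float(np.mean((baf <= extreme) | (baf >= 1 - extreme)))


def mismatch_profile(observations: pd.DataFrame, min_base_quality: int = 30,
                     min_mapq: int = 30, read_length: int | None = None) -> MismatchProfile:
    """Per-cycle mismatch frequency from per-base observations.

    ``observations`` columns: ``cycle`` (0-based position in the read),
    ``call_quality``, ``matches_reference`` (bool/0-1) and ``mapq`` of the
    carrying read.  Bases below ``min_base_quality`` or from reads below
    ``min_mapq`` are excluded from numerator and denominator alike.
    """
    ok = ((observations["call_quality"].to_numpy() >= min_base_quality)
          & (observations["mapq"].to_numpy() >= min_mapq))
    cycles = observations["cycle"].to_numpy()[ok]
    mism = ~observations["matches_reference"].to_numpy(dtype=bool)[ok]
    n_cycles = read_length if read_length is not None else (
        int(cycles.max()) + 1 if len(cycles) else 0)
    bases = np.bincount(cycles, minlength=n_cycles).astype(np.int64)
    mm = np.bincount(cycles[mism], minlength=n_cycles).astype(np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(bases > 0, mm / np.maximum(bases, 1), 0.0)
    return MismatchProfile(frequency=freq, mismatches=mm, bases=bases)


def ks_compare(sample_a: np.ndarray, sample_b: np.ndarray) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov-Smirnov test (asymptotic p)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("KS comparison needs two non-empty samples")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def compare_mismatch_profiles(profile_a: MismatchProfile,
                              profile_b: MismatchProfile,
                              unit: str = "cycle") -> tuple[float, float]:
    """KS comparison of two mismatch profiles.

    ``unit="cycle"`` (default) compares the per-cycle frequency vectors;
    ``unit="base"`` pools per-base mismatch indicators, approximated from
    the per-cycle counts.
    """
    if unit == "cycle":
        return ks_compare(profile_a.frequency, profile_b.frequency)
    if unit == "base":
        def expand(p: MismatchProfile) -> np.ndarray:
            ones = int(p.mismatches.sum())
            zeros = int(p.bases.sum()) - ones
            return np.concatenate([np.ones(ones), np.zeros(zeros)])
        return ks_compare(expand(profile_a), expand(profile_b))
    raise ValueError(f"unknown unit {unit!r}")
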