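"""Synthetic single-cell WGA sequencing data.

Generates truth genomes (copy-number segments, structural variants, SNP
genotypes), WGA-distorted bin counts, discordant read-pair tables (true SV
support plus chimeric amplification artefacts) and SNP allele counts — so
every stage of the toolkit can be exercised end-to-end without any
sequencing data.

The two bundled amplification profiles are calibrated to reported
characterisations of the respective chemistries:

* **MDA** (multiple displacement amplification): broad coverage (72% of
  the genome), chimeric artefacts dominated by inversion-like read pairs
  (98.3% of >=2-support signatures; TD 1.3%, DEL 0.3%, ITX 0.1%), an
  average 458-fold excess of signatures over the true genome structure, and
  low-recurrence deletion/tandem-duplication/inter-chromosomal artefacts
  (instigated late in the reaction, hence supported by few read pairs)
  versus proficient inversion artefact kinetics (heavy-tailed support).
* **PicoPlex** (PCR-based WGA): narrow coverage (36%), artefact spectrum
  with tandem duplications 54.1%, deletions 6.8%, inter-chromosomal 3.5%
  (inversions the remainder), 133-fold signature excess, heavy-tailed
  support for all classes (artefacts arise in the first amplification
  rounds, so thresholding on support does not remove them), TD artefact
  spans concentrated below 5 kb, and a higher nucleotide copy error rate.

All generators are pure functions of their inputs and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cnv import make_bins
from .pairs import (ITX_SPAN, PAIR_COLUMNS, RearrangementSignature,
                    SignatureClass)

DEFAULT_CHROM_LENGTHS = {"chr1": 50_000_000, "chr2": 50_000_000}
SV_CLASSES = ("DEL", "TD", "INV", "ITX")
DEFAULT_SV_CLASS_PROBS = {"DEL": 0.3, "TD": 0.3, "INV": 0.2, "ITX": 0.2}
DEFAULT_READ_LENGTH = 100
DEFAULT_INSERT_MIN = 200
DEFAULT_INSERT_MAX = 500


# ---------------------------------------------------------------------------
# WGA profiles

@dataclass(frozen=True)
class WGAProfile:
    """Parameterised artefact model of one whole-genome-amplification chemistry.

    ``artefact_spectrum`` is the class distribution of chimera signatures
    at the >=2-supporting-read-pair level (the level at which artefact
    spectra are observable after clustering); ``support_geom_p`` gives the
    per-class truncated-geometric parameter of the support count on
    {2, 3, ...} (mean 2 + (1-p)/p); ``artefact_span`` maps class to a
    list of (weight, lo, hi) log-uniform mixture components.
    """

    name: str
    coverage_breadth: float          # fraction of genome amplified (base level)
    amplicon_length: float           # mean amplified tract length, bp
    ado_rate: float                  # per-haplotype-locus allele dropout prob
    bias_sd: float                   # log2 SD of the smooth amplification bias field
    bias_corr_length: float          # correlation length of the bias field, bp
    gc_lin: float                    # linear GC-bias coefficient (natural log)
    gc_quad: float                   # quadratic GC-bias coefficient
    dispersion: float                # negative-binomial dispersion of counts
    artefact_spectrum: dict[str, float] = field(default_factory=dict)
    fold_excess: float = 0.0         # artefact signatures per true SV
    support_geom_p: dict[str, float] = field(default_factory=dict)
    artefact_span: dict[str, list[tuple[float, float, float]]] = field(default_factory=dict)
    nucleotide_error_rate: float = 0.0
    junk_pair_fraction: float = 0.02  # stray low-mapq / alt-concordant pairs

    def __post_init__(self):
        for r in (self.coverage_breadth, self.ado_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rates must be in [0,1], got {r}")
        if self.artefact_spectrum:
            total = sum(self.artefact_spectrum.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"artefact spectrum sums to {total}, not 1")

    @staticmethod
    def mda() -> "WGAProfile":
        wide = [(1.0, 1_000.0, 1_000_000.0)]
        return WGAProfile(
            name="MDA", coverage_breadth=0.72, amplicon_length=10_000.0,
            ado_rate=0.15, bias_sd=0.35, bias_corr_length=1_000_000.0,
            gc_lin=-2.0, gc_quad=-12.0, dispersion=0.2,
            artefact_spectrum={"INV": 0.983, "TD": 0.013, "DEL": 0.003, "ITX": 0.001},
            fold_excess=458.0,
            # late-reaction chimeras recur in few molecules -> low support for
            # DEL/TD/ITX; inversion chimeras form from the start -> heavy tail
            support_geom_p={"DEL": 2 / 3, "TD": 2 / 3, "ITX": 2 / 3, "INV": 0.2},
            artefact_span={"DEL": wide, "TD": wide, "INV": wide},
            nucleotide_error_rate=2e-4,
        )

    @staticmethod
    def picoplex() -> "WGAProfile":
        wide = [(1.0, 1_000.0, 1_000_000.0)]
        return WGAProfile(
            name="PicoPlex", coverage_breadth=0.36, amplicon_length=1_000.0,
            ado_rate=0.25, bias_sd=0.25, bias_corr_length=200_000.0,
            gc_lin=2.0, gc_quad=-10.0, dispersion=0.15,
            artefact_spectrum={"TD": 0.541, "DEL": 0.068, "ITX": 0.035, "INV": 0.356},
            fold_excess=133.0,
            support_geom_p={c: 0.2 for c in SV_CLASSES},
            artefact_span={
                # the vast majority of TD chimera spans fall below 5 kb
                "TD": [(0.9, 800.0, 5_000.0), (0.1, 5_000.0, 1_000_000.0)],
                "DEL": wide, "INV": wide,
            },
            nucleotide_error_rate=1.2e-3,
        )

    @staticmethod
    def none() -> "WGAProfile":
        """No amplification distortion: an (idealised) unamplified cell."""
        return WGAProfile(
            name="NONE", coverage_breadth=1.0, amplicon_length=1e12,
            ado_rate=0.0, bias_sd=0.0, bias_corr_length=1_000_000.0,
            gc_lin=0.0, gc_quad=0.0, dispersion=0.02,
            artefact_spectrum={}, fold_excess=0.0,
            support_geom_p={}, artefact_span={},
            nucleotide_error_rate=0.0, junk_pair_fraction=0.0,
        )

    @staticmethod
    def by_name(name: str) -> "WGAProfile":
        try:
            return {"mda": WGAProfile.mda, "picoplex": WGAProfile.picoplex,
                    "none": WGAProfile.none}[name.lower()]()
        except KeyError:
            raise ValueError(f"unknown WGA profile {name!r}") from None

    def with_overrides(self, **kwargs) -> "WGAProfile":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Truth genomes

@dataclass
class TruthGenome:
    """Ground truth a simulated cell is scored against.

    ``segments`` tiles each chromosome with per-haplotype integer copy
    numbers (columns chrom, start, end, cn_a, cn_b); ``svs`` holds the
    true rearrangements (sig_class, chrom1, pos1, chrom2, pos2, span,
    cn_change); ``snps`` holds positions, genotypes (AA/AB/BB) and which
    haplotype carries the B allele.  ``psi`` is the length-weighted mean
    total copy number — the cell's average ploidy per haploid reference
    unit against a diploid reference.
    """

    chrom_lengths: dict[str, int]
    segments: pd.DataFrame
    svs: pd.DataFrame
    snps: pd.DataFrame
    background_cn: int = 2

    @property
    def psi(self) -> float:
        seg = self.segments
        w = (seg["end"] - seg["start"]).to_numpy(dtype=float)
        cn = (seg["cn_a"] + seg["cn_b"]).to_numpy(dtype=float)
        return float((w * cn).sum() / w.sum())

    def cn_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Total integer CN at each position (haplotypes summed)."""
        seg = self.segments[self.segments["chrom"] == chrom]
        starts = seg["start"].to_numpy()
        cn = (seg["cn_a"] + seg["cn_b"]).to_numpy()
        idx = np.clip(np.searchsorted(starts, np.asarray(pos), side="right") - 1,
                      0, len(seg) - 1)
        return cn[idx]

    def hap_cn_at(self, chrom: str, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        seg = self.segments[self.segments["chrom"] == chrom]
        starts = seg["start"].to_numpy()
        idx = np.clip(np.searchsorted(starts, np.asarray(pos), side="right") - 1,
                      0, len(seg) - 1)
        return seg["cn_a"].to_numpy()[idx], seg["cn_b"].to_numpy()[idx]

    def bin_cn(self, bins: pd.DataFrame) -> np.ndarray:
        """True total CN per bin, evaluated at the bin midpoint."""
        out = np.empty(len(bins), dtype=np.int64)
        mid = ((bins["start"] + bins["end"]) // 2).to_numpy()
        chroms = bins["chrom"].to_numpy()
        for chrom in bins["chrom"].unique():
            sel = chroms == chrom
            out[sel] = self.cn_at(str(chrom), mid[sel])
        return out

    def consensus_fn(self):
        """(chrom, start, end) -> truth CN at the region midpoint."""
        def consensus(chrom: str, start: int, end: int) -> int:
            return int(self.cn_at(chrom, np.array([(start + end) // 2]))[0])
        return consensus

    def truth_signatures(self) -> list[RearrangementSignature]:
        """The true SVs as zero-width rearrangement signatures."""
        sigs = []
        for i, sv in self.svs.iterrows():
            p1, p2 = int(sv["pos1"]), int(sv["pos2"])
            sigs.append(RearrangementSignature(
                sig_class=SignatureClass(sv["sig_class"]),
                chromA=str(sv["chrom1"]), intervalA=(p1, p1),
                chromB=str(sv["chrom2"]), intervalB=(p2, p2),
                span=ITX_SPAN if sv["sig_class"] == "ITX" else p2 - p1,
                support=2, pair_ids=[f"truth{i}"],
            ))
        return sigs

    def find_anchor(self) -> tuple[str, int, int]:
        """Largest background-CN region, for anchoring the ploidy estimate."""
        seg = self.segments
        bg = seg[(seg["cn_a"] + seg["cn_b"]) == self.background_cn]
        if bg.empty:
            raise ValueError("no background-CN region to anchor on")
        best = bg.loc[(bg["end"] - bg["start"]).idxmax()]
        return str(best["chrom"]), int(best["start"]), int(best["end"])


def _tile_segments(chrom_lengths: dict[str, int],
                   cn_events: list[tuple[str, int, int, int]],
                   background: int = 2) -> pd.DataFrame:
    """Tile chromosomes into per-haplotype CN segments.

    ``cn_events`` are (chrom, start, end, delta) applied to haplotype A
    (a deletion removes the A copy, a duplication adds A copies).
    """
    rows = []
    for chrom, length in chrom_lengths.items():
        cuts = {0, length}
        for c, s, e, _d in cn_events:
            if c == chrom:
                cuts.update((s, e))
        bounds = sorted(cuts)
        for s, e in zip(bounds[:-1], bounds[1:]):
            cn_a = background // 2
            cn_b = background - background // 2
            for c, es, ee, d in cn_events:
                if c == chrom and es <= s and e <= ee:
                    cn_a += d
            if cn_a < 0:
                raise ValueError(f"copy number below zero on {chrom}:{s}-{e}")
            rows.append({"chrom": chrom, "start": s, "end": e,
                         "cn_a": cn_a, "cn_b": cn_b})
    return pd.DataFrame(rows)


def simulate_truth_genome(chrom_lengths: dict[str, int] | None = None,
                          n_svs: int = 8,
                          sv_span_range: tuple[float, float] = (2e6, 1e7),
                          class_probs: dict[str, float] | None = None,
                          snp_density: float = 1 / 3000,
                          het_fraction: float = 0.5,
                          sv_spec: list[dict] | None = None,
                          seed: int = 0) -> TruthGenome:
    """Random (or explicitly specified) truth genome.

    With ``sv_spec`` the given events (dicts with sig_class, chrom1, pos1
    and pos2/span, chrom2 for ITX) are used verbatim; otherwise ``n_svs``
    events are placed uniformly without overlap, spans log-uniform in
    ``sv_span_range``.  DEL lowers haplotype-A CN by one over its span,
    TD raises it by one; INV and ITX are balanced and leave CN unchanged.
    """
    chrom_lengths = dict(chrom_lengths or DEFAULT_CHROM_LENGTHS)
    class_probs = class_probs or DEFAULT_SV_CLASS_PROBS
    rng = np.random.default_rng(seed)
    chroms = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)

    svs: list[dict] = []
    if sv_spec is not None:
        for ev in sv_spec:
            ev = dict(ev)
            if "pos2" not in ev:
                ev["pos2"] = int(ev["pos1"] + ev["span"])
            ev.setdefault("chrom2", ev["chrom1"])
            ev["span"] = (ITX_SPAN if ev["sig_class"] == "ITX"
                          else int(ev["pos2"]) - int(ev["pos1"]))
            svs.append(ev)
    else:
        occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}

        def free(chrom: str, lo: int, hi: int) -> bool:
            return all(hi <= s or lo >= e for s, e in occupied[chrom])

        cls_names = list(class_probs)
        cls_p = np.array([class_probs[c] for c in cls_names])
        for i in range(n_svs):
            cls = cls_names[rng.choice(len(cls_names), p=cls_p / cls_p.sum())]
            for _attempt in range(1000):
                ci = rng.choice(len(chroms), p=lengths / lengths.sum())
                chrom = chroms[ci]
                if cls == "ITX":
                    cj = rng.choice([k for k in range(len(chroms)) if k != ci])
                    p1 = int(rng.integers(1_000_000, chrom_lengths[chrom] - 1_000_000))
                    p2 = int(rng.integers(1_000_000, chrom_lengths[chroms[cj]] - 1_000_000))
                    if free(chrom, p1 - 10_000, p1 + 10_000) and \
                       free(chroms[cj], p2 - 10_000, p2 + 10_000):
                        occupied[chrom].append((p1 - 10_000, p1 + 10_000))
                        occupied[chroms[cj]].append((p2 - 10_000, p2 + 10_000))
                        c1, c2 = chrom, chroms[cj]
                        if (c2, p2) < (c1, p1):  # canonical breakpoint order
                            c1, c2, p1, p2 = c2, c1, p2, p1
                        svs.append({"sig_class": cls, "chrom1": c1, "pos1": p1,
                                    "chrom2": c2, "pos2": p2})
                        break
                else:
                    span = int(np.exp(rng.uniform(np.log(sv_span_range[0]),
                                                  np.log(sv_span_range[1]))))
                    if span >= chrom_lengths[chrom] - 2_000_000:
                        continue
                    p1 = int(rng.integers(1_000_000,
                                          chrom_lengths[chrom] - span - 1_000_000))
                    if free(chrom, p1 - 10_000, p1 + span + 10_000):
                        occupied[chrom].append((p1 - 10_000, p1 + span + 10_000))
                        svs.append({"sig_class": cls, "chrom1": chrom, "pos1": p1,
                                    "chrom2": chrom, "pos2": p1 + span})
                        break
            else:
                raise RuntimeError("could not place SV without overlap; "
                                   "reduce n_svs or spans")
        for ev in svs:
            ev["span"] = (ITX_SPAN if ev["sig_class"] == "ITX"
                          else ev["pos2"] - ev["pos1"])

    cn_events = []
    for ev in svs:
        delta = {"DEL": -1, "TD": +1}.get(ev["sig_class"], 0)
        ev["cn_change"] = delta
        if delta:
            cn_events.append((ev["chrom1"], int(ev["pos1"]), int(ev["pos2"]), delta))
    # consistency: CN-affecting events must not overlap each other
    for c in chroms:
        evs = sorted([(s, e) for cc, s, e, _ in cn_events if cc == c])
        for (s1, e1), (s2, e2) in zip(evs[:-1], evs[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping CN-affecting SVs on {c}")
    segments = _tile_segments(chrom_lengths, cn_events)

    snp_rows = []
    for chrom, length in chrom_lengths.items():
        n = rng.poisson(length * snp_density)
        pos = np.sort(rng.choice(length, size=n, replace=False))
        het = rng.random(n) < het_fraction
        hom_b = (~het) & (rng.random(n) < 0.5)
        geno = np.where(het, "AB", np.where(hom_b, "BB", "AA"))
        b_hap = np.where(rng.random(n) < 0.5, "a", "b")
        snp_rows.append(pd.DataFrame({"chrom": chrom, "pos": pos,
                                      "genotype": geno, "b_hap": b_hap}))
    snps = pd.concat(snp_rows, ignore_index=True)
    return TruthGenome(chrom_lengths=chrom_lengths, segments=segments,
                       svs=pd.DataFrame(svs), snps=snps)


def simulate_sister_division(parent: TruthGenome, event_spec: list[dict],
                             seed: int = 0) -> tuple[TruthGenome, TruthGenome]:
    """Two daughter genomes one division after ``parent``.

    Each event dict has chrom, start, end, ``kind`` in {reciprocal,
    unbalanced_gain, unbalanced_loss} and optional ``k`` (copies, default
    1).  A reciprocal event adds +k to daughter A and -k to daughter B
    over the region (a mis-segregation); unbalanced events touch daughter
    A only.  Everything else is inherited unchanged.
    """
    ev_a, ev_b = [], []
    for ev in event_spec:
        k = int(ev.get("k", 1))
        region = (ev["chrom"], int(ev["start"]), int(ev["end"]))
        if ev["kind"] == "reciprocal":
            ev_a.append((*region, +k))
            ev_b.append((*region, -k))
        elif ev["kind"] == "unbalanced_gain":
            ev_a.append((*region, +k))
        elif ev["kind"] == "unbalanced_loss":
            ev_a.append((*region, -k))
        else:
            raise ValueError(f"unknown event kind {ev['kind']!r}")

    def apply(events) -> TruthGenome:
        seg = _apply_cn_events(parent.segments, events)
        return TruthGenome(chrom_lengths=dict(parent.chrom_lengths),
                           segments=seg, svs=parent.svs.copy(),
                           snps=parent.snps.copy(),
                           background_cn=parent.background_cn)

    return apply(ev_a), apply(ev_b)


def _apply_cn_events(segments: pd.DataFrame,
                     events: list[tuple[str, int, int, int]]) -> pd.DataFrame:
    """Split segments at event boundaries and add deltas to haplotype A."""
    rows = []
    for _, seg in segments.iterrows():
        cuts = {int(seg["start"]), int(seg["end"])}
        for c, s, e, _d in events:
            if c == seg["chrom"]:
                cuts.update(x for x in (s, e)
                            if seg["start"] < x < seg["end"])
        bounds = sorted(cuts)
        for s, e in zip(bounds[:-1], bounds[1:]):
            cn_a = int(seg["cn_a"])
            for c, es, ee, d in events:
                if c == seg["chrom"] and es <= s and e <= ee:
                    cn_a += d
            if cn_a < 0:
                raise ValueError(
                    f"event drives copy number below zero at {seg['chrom']}:{s}-{e}")
            rows.append({"chrom": seg["chrom"], "start": s, "end": e,
                         "cn_a": cn_a, "cn_b": int(seg["cn_b"])})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Depth simulation

def _smooth_field(n: int, corr_cells: float, sd: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Zero-mean Gaussian field with given SD and integral correlation scale.

    ``corr_cells`` is the integral of the autocorrelation function (the
    effective number of cells per independent block), so the variance of
    a mean over m >> corr_cells cells is ~ sd^2 * corr_cells / m.
    """
    if sd <= 0 or n == 0:
        return np.zeros(n)
    sigma_k = max(corr_cells / (2.0 * np.sqrt(np.pi)), 1e-6)
    white = rng.standard_normal(n + int(6 * sigma_k) + 1)
    from scipy.ndimage import gaussian_filter1d

    smooth = gaussian_filter1d(white, sigma=sigma_k, mode="wrap")
    smooth = smooth[:n]
    s = smooth.std()
    if s < 1e-12:
        return np.zeros(n)
    return (smooth - smooth.mean()) / s * sd


def _amplified_fraction(length: int, cell_edges: np.ndarray, breadth: float,
                        amplicon: float, rng: np.random.Generator) -> np.ndarray:
    """Fraction of each grid cell covered by amplified tracts.

    The genome alternates exponentially sized amplified / silent tracts
    (mean ``amplicon`` and ``amplicon*(1-breadth)/breadth`` bp), so the
    expected base-level amplified fraction equals ``breadth``.
    """
    if breadth >= 1.0:
        return np.ones(len(cell_edges) - 1)
    mean_off = amplicon * (1 - breadth) / breadth
    n_est = int(length / (amplicon + mean_off) * 1.5) + 10
    on = rng.exponential(amplicon, n_est)
    off = rng.exponential(mean_off, n_est)
    tracts = np.empty(2 * n_est)
    start_on = rng.random() < breadth
    tracts[0::2], tracts[1::2] = (on, off) if start_on else (off, on)
    edges = np.concatenate([[0.0], np.cumsum(tracts)])
    while edges[-1] < length:  # extremely unlikely; extend
        more_on = rng.exponential(amplicon, n_est)
        more_off = rng.exponential(mean_off, n_est)
        inter = np.empty(2 * n_est)
        inter[0::2], inter[1::2] = more_on, more_off
        edges = np.concatenate([edges, edges[-1] + np.cumsum(inter)])
    # cumulative amplified length at tract edges
    seg_len = np.diff(edges)
    is_on = np.zeros(len(seg_len), dtype=bool)
    is_on[0::2] = start_on
    is_on[1::2] = not start_on
    cum_amp = np.concatenate([[0.0], np.cumsum(seg_len * is_on)])
    cum_at = np.interp(cell_edges, edges, cum_amp)
    return np.diff(cum_at) / np.diff(cell_edges)


def _nbinom(rng: np.random.Generator, mean: np.ndarray,
            dispersion: float) -> np.ndarray:
    """Negative binomial draws with var = mean + dispersion * mean^2."""
    mean = np.maximum(np.asarray(mean, dtype=float), 0.0)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, np.maximum(mean, 1e-12) * dispersion)
    lam[mean <= 0] = 0.0
    return rng.poisson(lam)


def simulate_gc_track(chrom_lengths: dict[str, int], step: int,
                      seed: int, mean: float = 0.42, sd: float = 0.05,
                      corr_length: float = 200_000.0,
                      lo: float = 0.22, hi: float = 0.68) -> dict[str, np.ndarray]:
    """Smooth synthetic per-step-cell GC fractions (clipped to [lo, hi])."""
    rng = np.random.default_rng(seed)
    out = {}
    for chrom, length in chrom_lengths.items():
        n = int(np.ceil(length / step))
        field = _smooth_field(n, corr_length / step, sd, rng)
        out[chrom] = np.clip(mean + field, lo, hi)
    return out


def simulate_bin_counts(truth: TruthGenome, wga: WGAProfile, base_depth: float,
                        window: int = 10_000, step: int = 5_000,
                        seed: int = 0, ref_depth: float | None = None,
                        ref_dispersion: float = 0.02,
                        gc_track: dict[str, np.ndarray] | None = None) -> pd.DataFrame:
    """Bin table (chrom, start, end, gc, count_cell, count_ref).

    Counts are simulated on a ``step``-sized cell grid and summed into the
    overlapping sliding bins, so adjacent bins share reads the way real
    sliding-window counts do.  Expected cell-grid count::

        base_depth * (cells per bin)^-1 * (CN / psi) * exp(gc_bias(gc))
                   * 2**bias_field * amplified_fraction / coverage_breadth

    with negative-binomial sampling.  Dividing by the breadth models a
    fixed sequencing yield concentrating on the amplified part of the
    genome (amplified loci of a narrow-breadth product are covered
    proportionally deeper), so the genome-wide mean stays near
    ``base_depth``.  The reference is an unamplified diploid genome:
    unbiased negative binomial around ``ref_depth`` (default
    ``base_depth``).
    """
    rng = np.random.default_rng(seed)
    ref_depth = base_depth if ref_depth is None else ref_depth
    psi = truth.psi
    if gc_track is None:
        gc_track = simulate_gc_track(truth.chrom_lengths, step,
                                     seed=int(rng.integers(2**31)))
    cells_per_bin = window / step
    frames = []
    for chrom, length in truth.chrom_lengths.items():
        n = int(np.ceil(length / step))
        edges = np.minimum(np.arange(n + 1, dtype=float) * step, length)
        mids = ((edges[:-1] + edges[1:]) / 2).astype(np.int64)
        cn = truth.cn_at(chrom, mids).astype(float)
        gc = gc_track[chrom][:n]
        gc_fac = np.exp(wga.gc_lin * (gc - 0.42) + wga.gc_quad * (gc - 0.42) ** 2)
        bias = 2.0 ** _smooth_field(n, wga.bias_corr_length / step, wga.bias_sd, rng)
        amp = _amplified_fraction(length, edges, wga.coverage_breadth,
                                  wga.amplicon_length, rng)
        cell_w = np.diff(edges) / step  # truncated last cell
        mean_cell = ((base_depth / cells_per_bin) * (cn / psi) * gc_fac * bias
                     * (amp / wga.coverage_breadth) * cell_w)
        counts = _nbinom(rng, mean_cell, wga.dispersion)
        mean_ref = (ref_depth / cells_per_bin) * cell_w
        ref = _nbinom(rng, mean_ref, ref_dispersion)

        bins = make_bins({chrom: length}, window=window, step=step)
        b_start = bins["start"].to_numpy()
        b_end = bins["end"].to_numpy()
        ccum = np.concatenate([[0], np.cumsum(counts)])
        rcum = np.concatenate([[0], np.cumsum(ref)])
        gcum = np.concatenate([[0.0], np.cumsum(gc * np.diff(edges))])
        i0 = np.searchsorted(edges, b_start, side="left")
        i1 = np.searchsorted(edges, b_end, side="left")
        bins["count_cell"] = ccum[i1] - ccum[i0]
        bins["count_ref"] = rcum[i1] - rcum[i0]
        bins["gc"] = (gcum[i1] - gcum[i0]) / (b_end - b_start)
        frames.append(bins)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Read-pair simulation

def _draw_spans(cls: str, n: int, wga: WGAProfile,
                rng: np.random.Generator) -> np.ndarray:
    comps = wga.artefact_span.get(cls, [(1.0, 1_000.0, 1_000_000.0)])
    w = np.array([c[0] for c in comps])
    pick = rng.choice(len(comps), size=n, p=w / w.sum())
    lo = np.array([comps[i][1] for i in pick])
    hi = np.array([comps[i][2] for i in pick])
    return np.exp(rng.uniform(np.log(lo), np.log(hi))).astype(np.int64)


def _emit_pairs(cls: np.ndarray, chrom1: np.ndarray, bp1: np.ndarray,
                chrom2: np.ndarray, bp2: np.ndarray, support: np.ndarray,
                prefix: str, rng: np.random.Generator,
                insert_max: int, read_length: int) -> pd.DataFrame:
    """Expand per-signature breakpoints into jittered supporting read pairs."""
    rep = np.repeat(np.arange(len(cls)), support)
    cls_r = cls[rep]
    c1 = chrom1[rep]
    c2 = chrom2[rep]
    b1 = bp1[rep].astype(np.int64)
    b2 = bp2[rep].astype(np.int64)
    n = len(rep)
    spans = np.abs(b2 - b1)
    jit_cap = np.minimum(insert_max - read_length - 50,
                         np.maximum(spans // 3, 40))
    d1 = rng.integers(30, np.maximum(jit_cap, 31), n)
    d2 = rng.integers(30, np.maximum(jit_cap, 31), n)

    pos1 = np.empty(n, dtype=np.int64)
    pos2 = np.empty(n, dtype=np.int64)
    s1 = np.empty(n, dtype=object)
    s2 = np.empty(n, dtype=object)
    is_del = cls_r == "DEL"
    pos1[is_del] = b1[is_del] - d1[is_del]
    pos2[is_del] = b2[is_del] + d2[is_del]
    s1[is_del], s2[is_del] = "+", "-"
    is_td = cls_r == "TD"
    pos1[is_td] = b1[is_td] + d1[is_td]
    pos2[is_td] = b2[is_td] - d2[is_td]
    s1[is_td], s2[is_td] = "-", "+"
    is_inv = cls_r == "INV"
    # one junction orientation per signature, shared by its member pairs
    sig_orient = rng.random(len(cls)) < 0.5
    plus = sig_orient[rep] & is_inv
    minus = ~sig_orient[rep] & is_inv
    pos1[plus] = b1[plus] - d1[plus]
    pos2[plus] = b2[plus] - d2[plus]
    s1[plus] = s2[plus] = "+"
    pos1[minus] = b1[minus] + d1[minus]
    pos2[minus] = b2[minus] + d2[minus]
    s1[minus] = s2[minus] = "-"
    is_itx = cls_r == "ITX"
    sig_s1 = np.where(rng.random(len(cls)) < 0.5, "+", "-")
    sig_s2 = np.where(rng.random(len(cls)) < 0.5, "+", "-")
    off1 = rng.integers(30, insert_max - read_length, n)
    off2 = rng.integers(30, insert_max - read_length, n)
    pos1[is_itx] = b1[is_itx] + np.where(sig_s1[rep][is_itx] == "+", -off1[is_itx],
                                         off1[is_itx])
    pos2[is_itx] = b2[is_itx] + np.where(sig_s2[rep][is_itx] == "+", -off2[is_itx],
                                         off2[is_itx])
    s1[is_itx] = sig_s1[rep][is_itx]
    s2[is_itx] = sig_s2[rep][is_itx]

    starts = np.cumsum(support) - support
    ordinal = np.arange(n) - np.repeat(starts, support)
    pair_id = [f"{prefix}{r}_{o}" for r, o in zip(rep, ordinal)]
    df = pd.DataFrame({
        "chrom1": c1, "pos1": np.maximum(pos1, 0), "strand1": s1.astype(str),
        "chrom2": c2, "pos2": np.maximum(pos2, 0), "strand2": s2.astype(str),
        "mapq1": rng.integers(30, 61, n), "mapq2": rng.integers(30, 61, n),
        "alt_concordant": np.zeros(n, dtype=bool), "pair_id": pair_id,
    })
    return df


def _canonicalize(pairs: pd.DataFrame) -> pd.DataFrame:
    """Store each pair with the lower (chrom, pos) end first."""
    key1 = list(zip(pairs["chrom1"], pairs["pos1"]))
    key2 = list(zip(pairs["chrom2"], pairs["pos2"]))
    flip = np.array([k1 > k2 for k1, k2 in zip(key1, key2)])
    if flip.any():
        cols = [("chrom1", "chrom2"), ("pos1", "pos2"), ("strand1", "strand2"),
                ("mapq1", "mapq2")]
        out = pairs.copy()
        for a, b in cols:
            out.loc[flip, [a, b]] = pairs.loc[flip, [b, a]].to_numpy()
        return out
    return pairs


def simulate_read_pairs(truth: TruthGenome, wga: WGAProfile, depth: float = 100.0,
                        insert_min: int = DEFAULT_INSERT_MIN,
                        insert_max: int = DEFAULT_INSERT_MAX,
                        read_length: int = DEFAULT_READ_LENGTH,
                        sv_pair_rate: float = 0.15,
                        n_artefact_signatures: int | None = None,
                        seed: int = 0) -> pd.DataFrame:
    """Discordant read-pair table: true SV support plus WGA chimera artefacts.

    For each true SV, ``Poisson(sv_pair_rate * depth * CN_local / psi)``
    correctly oriented pairs are emitted when the junction locus was
    amplified (probability = coverage breadth), with positions jittered
    within the insert geometry.  Artefact signatures (count
    ``n_artefact_signatures``, default ``fold_excess`` times the number of
    true SVs) draw class, span and support from the WGA profile and are
    each emitted as that many near-duplicate pairs.  A small fraction of
    stray junk pairs carries low mapping quality or a concordant
    alternative alignment, to be removed by the refined-map filters.
    """
    rng = np.random.default_rng(seed)
    chroms = list(truth.chrom_lengths)
    lengths = np.array([truth.chrom_lengths[c] for c in chroms], dtype=float)
    frames = []

    # --- true SV support
    if len(truth.svs):
        sv = truth.svs
        amped = rng.random(len(sv)) < wga.coverage_breadth
        cn_local = np.array([
            truth.cn_at(str(r["chrom1"]), np.array([int(r["pos1"])]))[0]
            for _, r in sv.iterrows()], dtype=float)
        mean = sv_pair_rate * depth * cn_local / truth.psi * amped
        support = rng.poisson(mean)
        keep = support > 0
        if keep.any():
            frames.append(_emit_pairs(
                sv["sig_class"].to_numpy().astype(str)[keep],
                sv["chrom1"].to_numpy().astype(str)[keep],
                sv["pos1"].to_numpy()[keep],
                sv["chrom2"].to_numpy().astype(str)[keep],
                sv["pos2"].to_numpy()[keep],
                support[keep], "sv", rng, insert_max, read_length))

    # --- chimera artefacts
    n_art = (n_artefact_signatures if n_artefact_signatures is not None
             else int(round(wga.fold_excess * len(truth.svs))))
    if n_art > 0 and wga.artefact_spectrum:
        cls_names = list(wga.artefact_spectrum)
        probs = np.array([wga.artefact_spectrum[c] for c in cls_names])
        cls = np.array(cls_names, dtype=object)[
            rng.choice(len(cls_names), size=n_art, p=probs / probs.sum())].astype(str)
        ci = rng.choice(len(chroms), size=n_art, p=lengths / lengths.sum())
        chrom1 = np.array(chroms, dtype=object)[ci].astype(str)
        chrom2 = chrom1.copy()
        bp1 = np.empty(n_art, dtype=np.int64)
        bp2 = np.empty(n_art, dtype=np.int64)
        intra = cls != "ITX"
        spans = np.zeros(n_art, dtype=np.int64)
        for c in ("DEL", "TD", "INV"):
            m = cls == c
            spans[m] = _draw_spans(c, int(m.sum()), wga, rng)
        lim = lengths[ci] - spans - insert_max - 1
        bp1[intra] = (rng.random(intra.sum()) * np.maximum(lim[intra], 1)).astype(np.int64) \
            + insert_max
        bp2[intra] = bp1[intra] + spans[intra]
        itx = ~intra
        n_itx = int(itx.sum())
        if n_itx:
            cj = (ci[itx] + 1 + rng.integers(0, len(chroms) - 1, n_itx)) % len(chroms)
            chrom2[itx] = np.array(chroms, dtype=object)[cj].astype(str)
            bp1[itx] = rng.integers(insert_max, lengths[ci[itx]].astype(np.int64)
                                    - insert_max)
            bp2[itx] = rng.integers(insert_max, lengths[cj].astype(np.int64)
                                    - insert_max)
        p = np.array([wga.support_geom_p.get(c, 0.5) for c in cls])
        support = np.minimum(1 + rng.geometric(p), 50)
        frames.append(_emit_pairs(cls, chrom1, bp1, chrom2, bp2, support,
                                  "art", rng, insert_max, read_length))

    # --- junk pairs exercising the quality filters
    if frames and wga.junk_pair_fraction > 0:
        n_junk = int(sum(len(f) for f in frames) * wga.junk_pair_fraction)
        if n_junk:
            ci = rng.choice(len(chroms), size=n_junk, p=lengths / lengths.sum())
            cj = rng.choice(len(chroms), size=n_junk, p=lengths / lengths.sum())
            junk = pd.DataFrame({
                "chrom1": np.array(chroms, dtype=object)[ci].astype(str),
                "pos1": rng.integers(0, lengths[ci].astype(np.int64)),
                "strand1": np.where(rng.random(n_junk) < 0.5, "+", "-"),
                "chrom2": np.array(chroms, dtype=object)[cj].astype(str),
                "pos2": rng.integers(0, lengths[cj].astype(np.int64)),
                "strand2": np.where(rng.random(n_junk) < 0.5, "+", "-"),
                "mapq1": rng.integers(0, 30, n_junk),
                "mapq2": rng.integers(30, 61, n_junk),
                "alt_concordant": rng.random(n_junk) < 0.5,
                "pair_id": [f"junk_{i}" for i in range(n_junk)],
            })
            frames.append(junk)

    if not frames:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    pairs = pd.concat(frames, ignore_index=True)[PAIR_COLUMNS]
    return _canonicalize(pairs).reset_index(drop=True)


# ---------------------------------------------------------------------------
# SNP counts and mismatch observations

def simulate_snp_counts(truth: TruthGenome, wga: WGAProfile,
                        mean_depth: float = 30.0, seed: int = 0) -> pd.DataFrame:
    """Per-SNP allele counts (chrom, pos, ref_allele, alt_allele, a_reads, b_reads).

    Depth is negative binomial scaled by the local effective copy number
    after allele dropout and amplification; b_reads is binomial with the
    allele fraction implied by the surviving haplotype copies, perturbed
    by the profile's nucleotide copy error rate.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for chrom in truth.snps["chrom"].unique():
        snp = truth.snps[truth.snps["chrom"] == chrom]
        pos = snp["pos"].to_numpy()
        cn_a, cn_b = truth.hap_cn_at(str(chrom), pos)
        n = len(snp)
        amped = rng.random(n) < wga.coverage_breadth
        drop_a = rng.random(n) < wga.ado_rate
        drop_b = rng.random(n) < wga.ado_rate
        eff_a = np.where(drop_a, 0, cn_a)
        eff_b = np.where(drop_b, 0, cn_b)
        total = (eff_a + eff_b) * amped
        depth = _nbinom(rng, mean_depth * total / 2.0, wga.dispersion)
        geno = snp["genotype"].to_numpy()
        b_on_a = (snp["b_hap"] == "a").to_numpy()
        b_copies = np.where(geno == "BB", eff_a + eff_b,
                            np.where(geno == "AB",
                                     np.where(b_on_a, eff_a, eff_b), 0))
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(total > 0, b_copies / np.maximum(total, 1), 0.0)
        e = wga.nucleotide_error_rate
        p = p * (1 - e) + (1 - p) * e
        b_reads = rng.binomial(depth, p)
        rows.append(pd.DataFrame({
            "chrom": chrom, "pos": pos, "ref_allele": "A", "alt_allele": "B",
            "a_reads": depth - b_reads, "b_reads": b_reads,
        }))
    return pd.concat(rows, ignore_index=True)


def simulate_mismatch_observations(wga: WGAProfile, n_bases_per_cycle: int = 5000,
                                   read_length: int = DEFAULT_READ_LENGTH,
                                   seed: int = 0) -> pd.DataFrame:
    """Per-base records (cycle, call_quality, matches_reference, mapq).

    The nucleotide copy error rate ramps along the read (late cycles are
    worse), averaging the profile's rate.  A tail of low-quality bases and
    low-mapq reads is included so quality filtering is exercised; those
    bases carry an elevated error rate.
    """
    rng = np.random.default_rng(seed)
    base_rate = max(wga.nucleotide_error_rate, 1e-5)
    cycles = np.repeat(np.arange(read_length), n_bases_per_cycle)
    n = len(cycles)
    ramp = 0.6 + 0.8 * cycles / max(read_length - 1, 1)
    qual = np.where(rng.random(n) < 0.9, rng.integers(30, 41, n),
                    rng.integers(10, 30, n))
    mapq = np.where(rng.random(n) < 0.95, 60, rng.integers(0, 30, n))
    rate = base_rate * ramp * np.where(qual < 30, 20.0, 1.0)
    mismatch = rng.random(n) < np.minimum(rate, 0.5)
    return pd.DataFrame({"cycle": cycles, "call_quality": qual,
                         "matches_reference": ~mismatch, "mapq": mapq})
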