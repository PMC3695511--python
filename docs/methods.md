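# Methods

This note records the models, parameter choices and numerical decisions
behind `scpem`, and what the synthetic benchmarks do and do not
demonstrate.

## Depth-based copy-number model

A single cell's WGA product and a deep non-amplified reference are
counted in sliding windows (default 10 kb advanced every 5 kb; a 50-kb /
25-kb grid is available for low-coverage material).  Counting positions
with mapping quality below 30 are ignored.  Bins are dropped when both
samples have zero counts (no information) or when GC < 28% (coverage in
extremely AT-rich windows is too erratic to normalise).

The logR of bin *i* uses library-size scaling over kept bins with a
pseudocount of 0.5 on both counts — zero-count cell bins then map to a
large negative but finite logR rather than −∞.  Because of the
pseudocount, uniform rescaling of the cell's library cancels only up to
O(pc / count); at typical depths the called copy numbers are invariant.

**GC correction.**  WGA imprints a smooth depth trend in GC.  The trend
is estimated by a robust (Tukey-bisquare M-estimator) regression of logR
on a cubic B-spline basis in GC, with interior knots at GC quantiles (the
number of knots derived from the `loess_span` parameter, default 0.3),
then subtracted, and the residual profile is centred on its genome-wide
median.  Two properties motivated the basis-regression design over a
classic loess smoother:

* *Robustness*: single-cell logR has a heavy left tail (dropout bins).
  A least-squares smoother is dragged toward the tail wherever low-GC
  and low-coverage coincide, and the over-correction then reappears as
  megabase-scale spatially coherent shifts (GC is spatially correlated);
  the M-estimator ignores the tail.
* *Exact idempotency*: for any translation-equivariant regression whose
  span includes constants, re-correcting an already corrected profile is
  a no-op up to solver tolerance.  A loess smoother is not a projection
  and fails this; the spline fit satisfies it to machine precision,
  which makes the correction safely re-runnable in pipelines.

A conventional lowess fit is available as `method="lowess"`.

**Segmentation.**  PCF minimises the within-segment sum of squares plus
γ per breakpoint.  The default penalty stays at γ = 25 (5–10 for small
CNV hunting; larger values for low-coverage 50-kb grids).  Instead of the
usual fast heuristic, the objective is solved exactly by an O(n²) dynamic
program — on a 10,000-bin chromosome this costs well under a second, the
result is checkable against exhaustive enumeration, and an optional
banded mode (`max_seg_bins`) restores O(n·L) if ever needed.  Ties are
broken toward the leftmost optimal predecessor.  The input is segmented
as-is (no winsorisation; the robust GC fit already limits outlier
leverage, and remaining single-bin dropout outliers cost less than 2γ so
they cannot open interior breakpoints).  Filtered bins are absent from
the fitted vector; gaps of ≤ 5 consecutive dropped bins are stitched
over, longer gaps force a segment boundary.  With overlapping bins a
breakpoint's bp position is reported as the midpoint between the
adjacent segments' boundary bin starts.

**Integer copy number.**  `CN = round(2^logR · Ψ)` (half-up, floored at
0), with Ψ anchored on a user-supplied region of known copy number.
Because mean log-depth sits below log mean-depth for noisy bins (Jensen),
the anchor *mean* logR absorbs the same skew as segment means do, so the
bias cancels in the CN conversion; Ψ estimates therefore run slightly
above the length-weighted truth ploidy without harming integer calls.

## Rearrangement model

Orientation conventions follow standard Illumina FR paired-end geometry
(records canonicalised with the lower coordinate first): forward/reverse
within the insert bounds is concordant; beyond the upper bound, a
deletion signature; everted pairs, tandem duplication; same-strand,
inversion; different chromosomes, inter-chromosomal.  Short-insert
forward/reverse pairs are treated as concordant — small insertions are
out of scope.  Insert bounds default to 200–500 bp and are parameters,
not estimates.

Filtering drops a pair when either end overlaps the pile-up blacklist or
repeat panel (either-end overlap is the conservative reading), either
chromosome is mitochondrial, the pair could realign concordantly
elsewhere, or min(mapq) < 30.  A helper derives a pile-up blacklist from
reference-sample bins exceeding mean + 5 SD depth; curated panels can be
supplied instead.  Clustering is single linkage within (class, strand
pattern, chromosome pair): two pairs join when both coordinates differ by
at most `join_distance` (default 1000 bp ≈ insert upper bound plus
slack).  Single
linkage was chosen over more elaborate schemes because it is order-invariant and
conservative (it never splits a clump of near-duplicate chimera copies).
After clustering, signatures matching a germline reference map (same
class, both sides within 1 kb) are removed.  Inter-chromosomal
signatures have no span; they are stored with span −1 and are exempt
from span thresholds.

Map-vs-map matching is greedy one-to-one by increasing total per-side
interval distance, requiring identical class and chromosomes and both
sides within `match_tolerance` (default 10 kb; 100 kb is used where an
analysis mirrors the 100-kb copy-number-breakpoint concordance rule).
PPV at a threshold is undefined (NaN), not zero, when no query signature
survives.

## Simulator

The generator is the package's study-condition definition: its defaults
*are* the reported characterisations of the chemistries where those
exist, and stated choices elsewhere.

Printed calibrations (fixed):

| parameter | MDA | PicoPlex |
|---|---|---|
| genome breadth (base-level) | 0.72 | 0.36 |
| artefact spectrum (≥2-support) | INV .983 / TD .013 / DEL .003 / ITX .001 | TD .541 / DEL .068 / ITX .035 / INV .356 (residual) |
| signature fold-excess | 458× | 133× |
| TD artefact spans | log-uniform 1 kb–1 Mb | 90% log-uniform 0.8–5 kb |

Package choices (with rationale):

* **Support-count kinetics.**  Artefact support counts are truncated
  geometric on {2, 3, …} — the level at which artefact spectra are
  observed after clustering.  MDA DEL/TD/ITX chimeras arise late in the
  reaction and recur in few molecules: mean 2.5 (p = 2/3).  MDA
  inversions and all PicoPlex artefacts arise early: mean 6 (p = 0.2).
  This reproduces the operational finding that support
  thresholding cleans MDA maps for DEL/TD/ITX but cannot clean the
  inversion channel or PicoPlex maps.
* **Coverage breadth** is modelled at amplicon resolution, not bin
  resolution: the genome alternates exponential amplified/silent tracts
  (mean amplified tract 10 kb for MDA's long hyperbranched amplicons,
  1 kb for PicoPlex's short PCR amplicons) with base-level amplified
  fraction equal to the breadth.  A fixed sequencing yield concentrates
  on the amplified fraction (expected depth divides by breadth), so
  narrow-breadth products are covered deeper where covered at all — as
  observed for PicoPlex.
* **Amplification bias field**: multiplicative 2^N where N is a smooth
  Gaussian field, parameterised by its SD in log2 and its *integral*
  correlation scale.  MDA: sd 0.35 at 1 Mb (megabase-scale waviness;
  MDA depth profiles are the less accurate ones).  PicoPlex: sd 0.25 at
  200 kb — fine-grained unevenness whose segment-scale mean averages
  out, matching the observation that PCR-WGA copy-number profiles are
  the more accurate ones.  The amplitudes were fixed by a design-stage
  variance analysis: a segment of m bins with per-block field variance
  σ² and k independent blocks has mean error ≈ σ/√k, which must sit ≥3
  SD below the 0.32-log2 integer-rounding boundary for multi-Mb
  segments; blockwise fields at σ ≥ 0.5 provably violate this for any γ
  and were rejected.
* **Counts** are negative binomial (dispersion 0.2 MDA / 0.15 PicoPlex /
  0.02 unamplified reference), simulated on the 5-kb half-bin grid and
  summed into sliding bins so adjacent bins share counts exactly as real
  sliding windows share reads.  GC bias is exp-quadratic in GC around
  0.42 (MDA AT-favouring, PicoPlex GC-favouring); the synthetic GC track
  is a smooth field (mean 0.42, sd 0.05, 200-kb scale, clipped to
  0.22–0.68) so that the sub-28% filter is exercised.
* **Allele dropout** 0.15 (MDA) / 0.25 (PicoPlex) per haplotype-locus;
  nucleotide copy error 2×10⁻⁴ / 1.2×10⁻³ with a cycle ramp (×0.6 at the
  first cycle to ×1.4 at the last).
* **True SV support** is Poisson with mean `sv_pair_rate · depth ·
  CN_local / Ψ` when the junction locus was amplified (probability =
  breadth); `sv_pair_rate` defaults to 0.15, putting the mean at ~15
  pairs at depth 100 so that threshold curves remain informative across
  the 2–20 range.
* **Default test genome**: two 50-Mb chromosomes (minute-scale runs),
  ~8 CNV-scale SVs of 2–10 Mb, SNPs every ~3 kb with 50% heterozygosity.
  Spectrum/fold-excess benchmarks use two 500-Mb chromosomes instead:
  at 20,000+ artefact signatures the default genome's signature density
  would be ~30× that of a real 3-Gb genome and independent chimeras
  begin to merge during clustering, distorting the spectra; the larger
  genome restores realistic sparsity at unchanged cost.

## What the benchmarks show — and what they do not

The acceptance-style checks demonstrate that classification, clustering,
filtering, thresholding, segmentation and integration are *faithful*:
when data is generated under the reported artefact characterisations,
the pipeline recovers those characterisations end-to-end (spectra,
fold-excess, threshold-curve shapes, ≥99%/≥90% integer-CN recovery
without/with WGA distortion, sister-event labelling, LOH behaviour).
They do not validate the simulator against real WGA libraries: real
chimera geometry, mappability structure, repeat-driven pile-ups and
reference-genome idiosyncrasies are not modelled, and headline figures
obtainable only from real cells (genome-wide concordance, per-cell
sensitivities) depend on controlled-access data and are out of scope.  Runtime-driven scale choices (50-Mb chromosomes,
20,000-signature maps) are stated above as package defaults.

## Degenerate inputs and numerical corners

* All-equal GC or fewer than 50 kept bins: GC fit is skipped (warning),
  median centring still applies.
* All-zero cell or reference counts over kept bins: error.
* NaN in a segmentation input: error (filter first).
* Empty validated set (sensitivity) or empty reference event set
  (breakpoint concordance): error; empty query at a threshold: NaN.
* PCF ties: leftmost-optimal predecessor wins, deterministically.
* `integer_cn` rounds half up (2.5 → 3), floors at zero.
* All randomness flows through `numpy.random.default_rng(seed)`; every
  generator is a pure function of (inputs, seed), and the pipeline
  derives per-stage streams from a single seed.

## Known limitations

* Split-read/soft-clip evidence, junction assembly and insert-size
  estimation from alignments are out of scope; insert bounds are
  parameters.
* Small insertions are folded into the concordant class.
* The sister-cell consensus profile is a required input (truth profile
  in simulation; a subclone or modal profile in practice).
* SAM ingestion extracts positions and improper pairs only; evaluating
  alternative concordant alignments needs aligner-specific tags and is
  left upstream.
* The exact PCF solver is quadratic in bins per chromosome; for grids
  beyond ~10⁵ bins per chromosome use the banded mode.
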