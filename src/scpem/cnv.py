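"""Binned read-depth copy-number profiling of single-cell WGA sequencing.

The depth arm of the toolkit: a sliding-window bin grid over the genome,
per-bin read counts for the amplified single cell and a non-WGA reference,
a library-size-normalised log2 ratio (logR), GC-bias correction and median
centring.  Downstream segmentation and integer-copy-number conversion live
in :mod:`scpem.pcf`.

Bin tables are plain :class:`pandas.DataFrame` objects with columns
``chrom, start, end, gc, count_cell, count_ref`` (coordinates 0-based,
half-open).  Sliding bins overlap: with the default 10-kb window advanced
in 5-kb steps every genomic position is covered by up to two bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BIN_COLUMNS = ["chrom", "start", "end", "gc", "count_cell", "count_ref"]

DEFAULT_WINDOW = 10_000
DEFAULT_STEP = 5_000
DEFAULT_GC_MIN = 0.28
DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_LOESS_SPAN = 0.3


@dataclass
class LogRProfile:
    """Per-bin logR values plus the mask of bins that survived filtering.

    ``logr`` has one entry per *kept* bin, aligned with
    ``bins[kept_mask]``.  After :func:`gc_correct_and_center` the median
    of ``logr`` is zero.
    """

    bins: pd.DataFrame
    logr: np.ndarray
    kept_mask: np.ndarray
    gc_corrected: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def kept_bins(self) -> pd.DataFrame:
        return self.bins.loc[self.kept_mask]

    def __len__(self) -> int:  # number of kept bins
        return int(self.kept_mask.sum())


def make_bins(chrom_lengths: dict[str, int], window: int = DEFAULT_WINDOW,
              step: int = DEFAULT_STEP) -> pd.DataFrame:
    """Build the sliding-window bin grid (counts zeroed).

    Per chromosome, a new ``window``-bp bin starts every ``step`` bp at
    0, step, 2*step, ...; the final bin is truncated at the chromosome
    end.  Every position below the chromosome length is covered by at
    least one bin.
    """
    if window <= 0 or step <= 0:
        raise ValueError(f"window and step must be positive, got {window}/{step}")
    if step > window:
        raise ValueError(f"step ({step}) must not exceed window ({window})")
    frames = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"non-positive length for chromosome {chrom!r}")
        starts = np.arange(0, length, step, dtype=np.int64)
        # drop trailing starts that begin past the end (cannot happen with
        # arange < length) and keep only bins adding new coverage
        ends = np.minimum(starts + window, length)
        keep = starts < ends
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "start": starts[keep],
            "end": ends[keep],
            "gc": np.nan,
            "count_cell": 0,
            "count_ref": 0,
        }))
    if not frames:
        return pd.DataFrame(columns=BIN_COLUMNS)
    return pd.concat(frames, ignore_index=True)[BIN_COLUMNS]


def filter_bins(bins: pd.DataFrame, gc_min: float = DEFAULT_GC_MIN) -> np.ndarray:
    """Mask of analysable bins.

    A bin is discarded when its read count is zero in *both* the cell and
    the reference, or when its GC fraction is below ``gc_min`` (default
    28%, the regime where count data is too sparse to normalise).
    """
    both_zero = (bins["count_cell"].to_numpy() == 0) & (bins["count_ref"].to_numpy() == 0)
    low_gc = bins["gc"].to_numpy() < gc_min
    return ~(both_zero | low_gc)


def compute_logr(bins: pd.DataFrame, kept_mask: np.ndarray,
                 pseudocount: float = DEFAULT_PSEUDOCOUNT) -> LogRProfile:
    """Raw (pre-correction) logR of cell depth versus reference depth.

    Library sizes are equalised CNVseq-style by converting counts to
    within-kept-bin fractions; a pseudocount keeps zero-count bins
    finite::

        logr_i = log2( ((c_i+pc) / sum(c+pc)) / ((r_i+pc) / sum(r+pc)) )
    """
    kept = bins.loc[kept_mask]
    c = kept["count_cell"].to_numpy(dtype=float) + pseudocount
    r = kept["count_ref"].to_numpy(dtype=float) + pseudocount
    if kept["count_cell"].sum() <= 0:
        raise ValueError("all-zero cell counts over kept bins")
    if kept["count_ref"].sum() <= 0:
        raise ValueError("all-zero reference counts over kept bins")
    logr = np.log2((c / c.sum()) / (r / r.sum()))
    if not np.all(np.isfinite(logr)):
        raise ValueError("non-finite logR; check counts and pseudocount")
    return LogRProfile(bins=bins, logr=logr, kept_mask=np.asarray(kept_mask, bool),
                       meta={"pseudocount": pseudocount})


def _spline_design(gc: np.ndarray, span: float) -> np.ndarray | None:
    """Cubic B-spline design matrix with interior knots at GC quantiles.

    Least-squares regression on this basis is an orthogonal projection,
    which makes the GC correction exactly idempotent — re-correcting an
    already corrected profile is a no-op.
    """
    from scipy.interpolate import BSpline

    n_interior = max(1, round(1.0 / span))
    qs = np.linspace(0, 1, n_interior + 2)[1:-1]
    interior = np.quantile(gc, qs)
    lo, hi = gc.min(), gc.max()
    if hi - lo < 1e-9:
        return None
    k = 3
    t = np.concatenate([[lo] * (k + 1), interior, [hi] * (k + 1)])
    if np.any(np.diff(t) < 0):
        return None
    n_basis = len(t) - k - 1
    design = np.empty((len(gc), n_basis))
    for j in range(n_basis):
        coef = np.zeros(n_basis)
        coef[j] = 1.0
        design[:, j] = BSpline(t, coef, k, extrapolate=False)(gc)
    design = np.nan_to_num(design)
    return design


def fit_gc_trend(logr: np.ndarray, gc: np.ndarray, span: float = DEFAULT_LOESS_SPAN,
                 method: str = "spline") -> np.ndarray:
    """Fitted GC trend evaluated at every bin.

    ``method="spline"`` (default) fits a robust regression of logR on a
    cubic B-spline basis in GC (Tukey-bisquare M-estimator), so that the
    heavy left tail of dropout-affected bins cannot drag the trend;
    ``method="lowess"`` uses the classic locally weighted regression
    (statsmodels) with fraction ``span``.
    """
    if method == "lowess":
        from statsmodels.nonparametric.smoothers_lowess import lowess

        order = np.argsort(gc, kind="stable")
        fitted = lowess(logr[order], gc[order], frac=span, it=2,
                        return_sorted=False)
        out = np.empty_like(fitted)
        out[order] = fitted
        return out
    import statsmodels.api as sm

    design = _spline_design(gc, span)
    if design is None:
        raise ValueError("degenerate GC values; cannot fit a trend")
    res = sm.RLM(logr, design, M=sm.robust.norms.TukeyBiweight()).fit(
        maxiter=200, tol=1e-10)
    return design @ res.params


def gc_correct_and_center(profile: LogRProfile, span: float = DEFAULT_LOESS_SPAN,
                          min_bins: int = 50, method: str = "spline") -> LogRProfile:
    """Remove the GC-bias trend from logR and centre the median at zero.

    WGA reactions amplify GC-balanced fragments preferentially, imprinting
    a smooth depth trend in GC that would masquerade as copy number.  The
    trend is estimated by a smooth fit of logR against per-bin GC, then
    subtracted; the residual profile is shifted so its genome-wide median
    is exactly zero (a diploid-dominated genome then sits at logR 0).

    Degenerate inputs (all-equal GC, or fewer than ``min_bins`` kept bins)
    skip the fit and only centre, with a warning.
    """
    gc = profile.kept_bins["gc"].to_numpy(dtype=float)
    logr = profile.logr.astype(float)
    fitted = np.zeros_like(logr)
    if len(logr) < min_bins or np.ptp(gc) < 1e-9:
        warnings.warn("GC fit skipped (too few bins or degenerate GC); centring only",
                      stacklevel=2)
    else:
        fitted = fit_gc_trend(logr, gc, span=span, method=method)
    resid = logr - fitted
    resid = resid - np.median(resid)
    return LogRProfile(bins=profile.bins, logr=resid, kept_mask=profile.kept_mask,
                       gc_corrected=True,
                       meta={**profile.meta, "loess_span": span, "gc_method": method})
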