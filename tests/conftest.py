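import numpy as np
import pandas as pd
import pytest

import scpem
from scpem.simulate import WGAProfile, simulate_bin_counts, simulate_truth_genome


@pytest.fixture(scope="session")
def small_truth():
    """Truth genome with one 8-Mb deletion and one 6-Mb duplication."""
    return simulate_truth_genome(sv_spec=[
        {"sig_class": "DEL", "chrom1": "chr1", "pos1": 10_000_000,
         "span": 8_000_000},
        {"sig_class": "TD", "chrom1": "chr2", "pos1": 20_000_000,
         "span": 6_000_000},
    ], seed=7)


@pytest.fixture(scope="session")
def clean_profile(small_truth):
    """Corrected logR profile of an unamplified cell at depth 200."""
    bins = simulate_bin_counts(small_truth, WGAProfile.none(), 200, seed=9)
    kept = scpem.filter_bins(bins)
    profile = scpem.compute_logr(bins, kept)
    return bins, scpem.gc_correct_and_center(profile)


def toy_bins(counts_cell, counts_ref, gc=0.45, window=10_000):
    n = len(counts_cell)
    return pd.DataFrame({
        "chrom": "chr1",
        "start": np.arange(n) * window,
        "end": (np.arange(n) + 1) * window,
        "gc": gc if np.ndim(gc) else np.full(n, gc),
        "count_cell": counts_cell,
        "count_ref": counts_ref,
    })
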