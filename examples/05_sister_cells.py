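"""Reciprocal copy-number events in two sister cells.

A chromosome mis-segregation during one division gives complementary
gains and losses in the daughters; a replication-based gain appears in
one daughter only.  Both cells are called independently and their
deviations from the parental consensus profile are classified.
"""

import scpem
from scpem.integrate import reciprocal_events
from scpem.simulate import (WGAProfile, simulate_bin_counts,
                            simulate_sister_division, simulate_truth_genome)

parent = simulate_truth_genome(n_svs=0, seed=5)
daughter_a, daughter_b = simulate_sister_division(parent, [
    {"chrom": "chr1", "start": 10_000_000, "end": 22_000_000,
     "kind": "reciprocal", "k": 1},
    {"chrom": "chr2", "start": 5_000_000, "end": 12_000_000,
     "kind": "unbalanced_gain"},
], seed=6)


def call(truth, seed):
    bins = simulate_bin_counts(truth, WGAProfile.none(), 200, seed=seed)
    kept = scpem.filter_bins(bins)
    profile = scpem.gc_correct_and_center(scpem.compute_logr(bins, kept))
    segments = scpem.segment_profile(profile, gamma=25.0)
    psi = scpem.estimate_ploidy(profile, truth.find_anchor(), 2).psi
    return scpem.assign_segment_cn(segments, psi)


events = reciprocal_events(call(daughter_a, 7), call(daughter_b, 8),
                           parent.consensus_fn())
print("events relative to the parental consensus profile:")
for e in events:
    print(f"  {e.chrom}:{e.start:,}-{e.end:,}  {e.kind:>16}  "
          f"CN A={e.cn_cell_a}  B={e.cn_cell_b}  consensus={e.cn_consensus}")
# 'reciprocal' marks complementary gain/loss (mis-segregation in the
# preceding division); 'unbalanced_gain' is extra DNA in one daughter with
# no compensating loss in its sister.
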