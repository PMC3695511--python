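"""Rearrangement mapping under a storm of MDA chimera artefacts.

An MDA-amplified cell yields hundreds of artefact read-pair signatures
for every real rearrangement.  This example builds the refined paired-end
map for a cell carrying 200 true structural variants, then shows how
support-count thresholding separates real deletions, tandem duplications
and inter-chromosomal events from the chimeras — while inversion
artefacts resist thresholding entirely.
"""

from scpem.integrate import compute_ppv, compute_sensitivity
from scpem.pairs import PairedEndMap, build_reference_map, build_refined_map
from scpem.simulate import WGAProfile, simulate_read_pairs, simulate_truth_genome

GENOME = {"chr1": 500_000_000, "chr2": 500_000_000}

truth = simulate_truth_genome(chrom_lengths=GENOME, n_svs=200,
                              sv_span_range=(2e4, 5e5), snp_density=1e-9, seed=1)
pairs = simulate_read_pairs(truth, WGAProfile.mda(), depth=100, seed=1)
refined = build_refined_map(pairs)
reference = build_reference_map(PairedEndMap(signatures=truth.truth_signatures()))

print(f"discordant read pairs : {len(pairs):,}")
print(f"refined-map signatures: {len(refined):,} "
      f"({len(refined) / len(reference):.0f}-fold the true structure)")
print(f"class spectrum        : {refined.counts_by_class()}")

ppv = compute_ppv(refined, reference)
sens = compute_sensitivity(refined, truth.truth_signatures())
print("\nthreshold  PPV(DEL)  PPV(TD)  PPV(INV)  PPV(ITX)  sensitivity")
for t in (2, 4, 6, 8, 12):
    row = ppv.loc[t]
    print(f"{t:>9}  {row['DEL']:>8.2f}  {row['TD']:>7.2f}  {row['INV']:>8.3f}"
          f"  {row['ITX']:>8.2f}  {sens.loc[t]:>11.2f}")
# PPV for DEL/TD/ITX climbs toward 1 as the minimum read-pair support
# rises (late-reaction chimeras recur in few molecules); inversion PPV
# stays near zero and sensitivity decays as real variants are discarded.
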