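"""End-to-end orchestration of the simulate -> call -> integrate workflow.

:func:`run_pipeline` drives every stage on one configuration: synthetic
truth genome and cell data, depth-based copy-number calling, refined
paired-end map construction and thresholding, map-vs-truth benchmarking,
bait capture, artefact flagging, BAF/genotyping and mismatch profiling.
All outputs are plain text tables plus a JSON report and a provenance
manifest; reruns with the same configuration are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import baf as baf_mod
from . import cnv, integrate, io, pcf, simulate
from .pairs import FilterPanel, build_refined_map, build_reference_map, threshold_map

DEFAULT_CONFIG = {
    "seed": 1,
    "window": 10_000,
    "step": 5_000,
    "gamma": 25.0,
    "loess_span": 0.3,
    "pseudocount": 0.5,
    "gc_min": 0.28,
    "mapq_min": 30,
    "insert_min": 200,
    "insert_max": 500,
    "join_distance": 1_000,
    "min_span": 5_000,
    "bait_radius": 50_000,
    "threshold_min": 2,
    "threshold_max": 20,
    "match_tolerance": 10_000,
    "wga_profile": "picoplex",
    "base_depth": 100.0,
    "snp_depth": 30.0,
    "n_svs": 8,
    "sv_span_range": (2e6, 1e7),
    "chrom_lengths": None,
}


def run_pipeline(config: dict | None = None, outdir: str | Path = "scpem_run") -> dict:
    """Run the full synthetic workflow; returns the report dict.

    ``config`` overrides :data:`DEFAULT_CONFIG` keys.  Artifacts written
    under ``outdir``: bin table, segment calls, refined/thresholded maps,
    PPV and sensitivity curves, bait captures, BAF table, mismatch
    profile, report.json and provenance.json.
    """
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(2**31))  # per-stage streams from one seed

    wga = simulate.WGAProfile.by_name(cfg["wga_profile"])
    truth = simulate.simulate_truth_genome(
        chrom_lengths=cfg["chrom_lengths"], n_svs=int(cfg["n_svs"]),
        sv_span_range=tuple(cfg["sv_span_range"]), seed=sub())
    io.write_truth_manifest(truth, outdir / "truth")

    # depth arm
    bins = simulate.simulate_bin_counts(truth, wga, cfg["base_depth"],
                                        window=int(cfg["window"]),
                                        step=int(cfg["step"]), seed=sub())
    io.write_bins(bins, outdir / "bins.tsv")
    kept = cnv.filter_bins(bins, gc_min=cfg["gc_min"])
    profile = cnv.compute_logr(bins, kept, pseudocount=cfg["pseudocount"])
    profile = cnv.gc_correct_and_center(profile, span=cfg["loess_span"])
    segments = pcf.segment_profile(profile, gamma=cfg["gamma"])
    anchor = cfg.get("anchor_region") or truth.find_anchor()
    psi = pcf.estimate_ploidy(profile, anchor, int(cfg.get("anchor_cn", 2))).psi
    pcf.assign_segment_cn(segments, psi)
    io.write_segments(pcf.segments_frame(segments), outdir / "segments.tsv")

    # read-pair arm
    pairs = simulate.simulate_read_pairs(
        truth, wga, depth=cfg["base_depth"], insert_min=int(cfg["insert_min"]),
        insert_max=int(cfg["insert_max"]), seed=sub())
    io.write_pairs(pairs, outdir / "pairs.tsv")
    panel = cfg.get("panel") or FilterPanel()
    refined = build_refined_map(pairs, panel, insert_min=int(cfg["insert_min"]),
                                insert_max=int(cfg["insert_max"]),
                                join_distance=int(cfg["join_distance"]),
                                mapq_min=int(cfg["mapq_min"]))
    io.write_map(refined, outdir / "refined_map.bedpe")
    reference = build_reference_map(_truth_map(truth))
    thresholds = range(int(cfg["threshold_min"]), int(cfg["threshold_max"]) + 1)
    ppv = integrate.compute_ppv(refined, reference, thresholds,
                                min_span=int(cfg["min_span"]),
                                match_tolerance=int(cfg["match_tolerance"]))
    io.write_table(ppv.reset_index(), outdir / "ppv.tsv")
    sens = integrate.compute_sensitivity(refined, truth.truth_signatures(),
                                         thresholds,
                                         match_tolerance=int(cfg["match_tolerance"]))
    io.write_table(sens.reset_index(), outdir / "sensitivity.tsv")

    # integration
    bps = pcf.segment_breakpoints(segments, profile)
    captured = integrate.bait_capture(refined, bps, radius=int(cfg["bait_radius"]))
    cap_rows = [{"class": c["signature"].sig_class.value,
                 "chromA": c["signature"].chromA,
                 "startA": c["signature"].intervalA[0],
                 "logr_step": c["logr_step"],
                 "consistent": c["consistent"]} for c in captured]
    io.write_table(pd.DataFrame(cap_rows, columns=["class", "chromA", "startA",
                                                   "logr_step", "consistent"]),
                   outdir / "bait_captures.tsv")
    gains = [s for s in segments
             if s.cn is not None and s.cn > truth.background_cn]
    flags = integrate.flag_pcr_pileup_gains(gains, refined)
    flag_rows = [{"chrom": f["segment"].chrom, "start": f["segment"].start_bp,
                  "end": f["segment"].end_bp, "n_tiny_td": f["n_tiny_td"],
                  "artefact": f["artefact"]} for f in flags]
    io.write_table(pd.DataFrame(flag_rows, columns=["chrom", "start", "end",
                                                    "n_tiny_td", "artefact"]),
                   outdir / "gain_flags.tsv")

    # SNP arm
    snps = simulate.simulate_snp_counts(truth, wga, mean_depth=cfg["snp_depth"],
                                        seed=sub())
    baf_table = baf_mod.compute_baf(snps)
    baf_table["genotype"] = baf_mod.call_genotypes(snps)
    io.write_table(baf_table, outdir / "baf.tsv")
    obs = simulate.simulate_mismatch_observations(wga, seed=sub())
    mm = baf_mod.mismatch_profile(obs)
    io.write_table(mm.frame(), outdir / "mismatch_profile.tsv")

    truth_bin_cn = truth.bin_cn(bins)[kept]
    called_bin_cn = pcf.bin_cn(profile, segments, psi)
    report = {
        "seed": seed,
        "wga_profile": wga.name,
        "psi_estimate": psi,
        "psi_truth": truth.psi,
        "n_segments": len(segments),
        "n_refined_signatures": len(refined),
        "n_reference_signatures": len(reference),
        "bin_cn_recovery": float(np.mean(called_bin_cn == truth_bin_cn)),
        "sensitivity_at_2": float(sens.iloc[0]),
        "n_bait_captured": len(captured),
        "genotype_call_rate": float((baf_table["genotype"] != "NOCALL").mean()),
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    io.write_provenance(outdir / "provenance.json",
                        {k: v for k, v in cfg.items() if k != "panel"})
    return report


def _truth_map(truth):
    from .pairs import PairedEndMap

    return PairedEndMap(signatures=truth.truth_signatures())
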