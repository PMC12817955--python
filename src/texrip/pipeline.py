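"""End-to-end orchestration: synthetic data -> all analysis stages -> report.

``run_demo`` generates a complete synthetic study (genome, ±TEX read-start
tracks, RIP-seq coverage, correlated expression tables), runs every analysis
stage, and writes the intermediate files plus a summary report comparing the
calls to the planted truth (sensitivity/precision per stage).  All randomness
derives from the single seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import expression as expr
from . import io as tio
from . import ripseq, sites, synthetic, transcripts

#: positional tolerance (nt) when matching a called site to a planted site
SITE_MATCH_TOL = 5


def _derive_seeds(seed: int, n: int) -> list[int]:
    """Deterministic child seeds, each below 2**31."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def match_sites(
    called: list[sites.SiteCall],
    planted: list[tuple[int, str, float]],
    tol: int = SITE_MATCH_TOL,
) -> tuple[float, float, int, int]:
    """(sensitivity, precision, n_true_positive, n_called) by position match."""
    called_pos = {(c.strand, c.position) for c in called}
    recovered = 0
    for pos, strand, _ in planted:
        if any(
            (strand, p) in called_pos for p in range(pos - tol, pos + tol + 1)
        ):
            recovered += 1
    tp_calls = 0
    planted_by_strand: dict[str, list[int]] = {}
    for pos, strand, _ in planted:
        planted_by_strand.setdefault(strand, []).append(pos)
    for c in called:
        near = planted_by_strand.get(c.strand, [])
        if any(abs(c.position - p) <= tol for p in near):
            tp_calls += 1
    sensitivity = recovered / len(planted) if planted else float("nan")
    precision = tp_calls / len(called) if called else float("nan")
    return sensitivity, precision, recovered, len(called)


def match_peaks(
    called: list[ripseq.InteractionPeak],
    planted: list[tuple[int, int, str, float]],
) -> tuple[float, float, float]:
    """(sensitivity, fdr, mean boundary error nt) for significant peaks."""
    sig = [p for p in called if p.significant]
    recovered = 0
    boundary_errors = []
    for start, end, strand, _ in planted:
        hits = [
            p for p in sig
            if p.strand == strand and min(p.end, end) - max(p.start, start) > 0
        ]
        if hits:
            recovered += 1
            best = max(hits, key=lambda p: min(p.end, end) - max(p.start, start))
            boundary_errors.append(
                (abs(best.start - start) + abs(best.end - end)) / 2.0
            )
    fp = 0
    for p in sig:
        if not any(
            p.strand == strand and min(p.end, end) - max(p.start, start) > 0
            for start, end, strand, _ in planted
        ):
            fp += 1
    sensitivity = recovered / len(planted) if planted else float("nan")
    fdr = fp / len(sig) if sig else 0.0
    mean_err = float(np.mean(boundary_errors)) if boundary_errors else float("nan")
    return sensitivity, fdr, mean_err


def run_demo(
    seed: int = 1,
    outdir: str | Path | None = None,
    genome_length: int = synthetic.DEFAULT_GENOME_LENGTH,
    n_genes: int | None = None,
    drna_depth: float = 50.0,
    background_rate: float = 0.5,
    rip_depth: float = 50.0,
    null: bool = False,
) -> dict:
    """Run the full synthetic pipeline; return (and optionally write) a summary.

    With ``null=True`` no signal is planted anywhere, so every stage should
    return zero calls at the default thresholds.
    """
    seeds = _derive_seeds(seed, 6)
    if n_genes is None:
        n_genes = synthetic.scaled_n_genes(genome_length)
    if null:
        sequence, truth = synthetic.make_truth(
            genome_length=genome_length, n_genes=n_genes,
            n_tss=0, n_tps=0, n_peaks=0, n_asrna=0, seed=seeds[0],
        )
    else:
        sequence, truth = synthetic.make_truth(
            genome_length=genome_length, n_genes=n_genes, seed=seeds[0]
        )
    annotation = truth.annotation()

    # --- stage 1: dRNA-seq site detection ---------------------------------
    drna = synthetic.simulate_drna_tracks(
        truth, depth=drna_depth, background_rate=background_rate, seed=seeds[1]
    )
    tss_calls: list[sites.SiteCall] = []
    tps_calls: list[sites.SiteCall] = []
    for strand in "+-":
        tss_calls += sites.call_sites(
            drna["+TEX"][strand], drna["-TEX"][strand], strand=strand
        )
        tps_calls += sites.call_tps(
            drna["+TEX"][strand], drna["-TEX"][strand], strand=strand
        )
    tss_calls = sites.apply_site_filters(tss_calls)
    tps_calls = sites.apply_site_filters(tps_calls)
    tss_calls = sites.classify_tss(tss_calls, annotation, truth.genome_length)
    tss_sens, tss_prec, _, _ = match_sites(tss_calls, truth.planted_tss)
    tps_sens, tps_prec, _, _ = match_sites(tps_calls, truth.planted_tps)

    # --- stage 2: transcript annotation -----------------------------------
    cands = transcripts.annotate_transcripts(
        tss_calls, truth.planted_tts, sequence, annotation
    )
    planted_t = {
        (s, e, strand) for _, s, e, strand, _ in truth.planted_transcripts
    }
    exact = sum(1 for c in cands if (c.start, c.end, c.strand) in planted_t)
    transcript_recovery = (
        exact / len(planted_t) if planted_t else float("nan")
    )

    # --- stage 3: RIP-seq peaks --------------------------------------------
    rip = synthetic.simulate_ripseq(truth, depth=rip_depth, seed=seeds[2])
    peaks: list[ripseq.InteractionPeak] = []
    for strand in "+-":
        lfc = ripseq.log2fc_track(rip["coip"][strand], rip["mock"][strand])
        raw = ripseq.find_peaks(lfc)
        peaks += ripseq.test_peaks(
            raw, rip["coip"][strand], rip["mock"][strand], strand=strand
        )
    merged_ann = tio.GenomeAnnotation(
        annotation.features
        + [
            tio.Feature(tid, "asRNA", s, e, strand, {"gene": g})
            for tid, s, e, strand, g in truth.planted_transcripts
        ]
    )
    peaks = ripseq.assign_targets(peaks, merged_ann)
    peaks = ripseq.classify_peak_positions(peaks, merged_ann)
    peak_sens, peak_fdr, peak_err = match_peaks(peaks, truth.planted_peaks)
    sig_peaks = ripseq.significant_peaks(peaks)
    gc_summary = None
    if sig_peaks:
        gc_res = ripseq.gc_background_test(sig_peaks, sequence)
        gc_summary = {
            "peak_median_gc": float(np.median(gc_res.peak_gc)),
            "background_median_gc": float(np.median(gc_res.background_gc)),
            "pvalue": gc_res.pvalue,
        }

    # --- stage 4: expression pairs -----------------------------------------
    pair_summary = None
    direction = None
    if truth.pair_truth:
        tables = synthetic.simulate_expression(truth.pair_truth, seed=seeds[3])
        lfc_m = synthetic.wide_lfc(tables["mrna"])
        lfc_a = synthetic.wide_lfc(tables["asrna"])
        pair_ann = tio.GenomeAnnotation(
            annotation.features
            + [
                tio.Feature(tid, "asRNA", s, e, strand)
                for tid, s, e, strand, _ in truth.planted_transcripts
            ]
        )
        pairs = expr.build_pairs(pair_ann)
        pairs = expr.correlate_pairs(pairs, lfc_m, lfc_a)
        truth_pcc = {(m, a): r for m, a, r in truth.pair_truth}
        errs = [
            abs(p.pcc - truth_pcc[(p.mrna_id, p.asrna_id)])
            for p in pairs
            if p.pcc is not None and (p.mrna_id, p.asrna_id) in truth_pcc
        ]
        pair_summary = {
            "n_pairs": len(pairs),
            "mean_abs_pcc_error": float(np.mean(errs)) if errs else float("nan"),
        }
        strong = [
            p for p in pairs
            if abs(truth_pcc.get((p.mrna_id, p.asrna_id), 0.0)) >= 0.9
        ]
        if strong:
            expected = {
                True: "positive", False: "negative",
            }
            acc = np.mean([
                p.corr_class
                == expected[truth_pcc[(p.mrna_id, p.asrna_id)] > 0]
                for p in strong
            ])
            pair_summary["class_accuracy_strong"] = float(acc)
        # direction agreement at one "timepoint" (first contrast)
        try:
            first = sorted(lfc_m.columns)[0]
            direction = asdict(
                expr.direction_agreement(pairs, lfc_m[first], lfc_a[first],
                                         timepoint=first)
            )
        except ValueError:
            direction = None

    # --- stage 5: integration ----------------------------------------------
    integration = None
    if truth.pair_truth:
        smap1 = {p.target_id for p in sig_peaks[: len(sig_peaks) // 2]
                 if p.target_id}
        smap2 = {p.target_id for p in sig_peaks[len(sig_peaks) // 2:]
                 if p.target_id}
        universe = {f.id for f in merged_ann}
        lfc_tables = {
            cid: lfc_m[cid].rename("log2fc").to_frame() for cid in lfc_m.columns[:3]
        }
        traj = expr.smap_group_trajectories(
            {"smap1": smap1, "smap2": smap2}, lfc_tables, universe
        )
        integration = {"n_trajectory_rows": int(len(traj))}

    summary = {
        "seed": seed,
        "genome_length": truth.genome_length,
        "sites": {
            "n_planted_tss": len(truth.planted_tss),
            "n_called_tss": len(tss_calls),
            "tss_sensitivity": tss_sens,
            "tss_precision": tss_prec,
            "n_planted_tps": len(truth.planted_tps),
            "n_called_tps": len(tps_calls),
            "tps_sensitivity": tps_sens,
            "tps_precision": tps_prec,
        },
        "transcripts": {
            "n_planted": len(truth.planted_transcripts),
            "n_annotated": len(cands),
            "exact_recovery": transcript_recovery,
        },
        "peaks": {
            "n_planted": len(truth.planted_peaks),
            "n_significant": len(sig_peaks),
            "sensitivity": peak_sens,
            "fdr": peak_fdr,
            "mean_boundary_error_nt": peak_err,
            "gc": gc_summary,
        },
        "pairs": pair_summary,
        "integration": {"direction": direction, "trajectories": integration},
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tio.write_fasta({"genome": sequence}, outdir / "genome.fa")
        tio.write_gff3(annotation, outdir / "genes.gff3")
        truth.write_manifest(outdir / "truth.tsv")
        for lib, by_strand in drna.items():
            for strand, reps in by_strand.items():
                tag = {"+": "fwd", "-": "rev"}[strand]
                for i, arr in enumerate(reps, start=1):
                    tio.write_bedgraph(
                        arr, outdir / f"drna_{lib.strip('+-')}"
                        f"{'_plus' if lib.startswith('+') else '_minus'}"
                        f"_{tag}_rep{i}.bedgraph"
                    )
        tio.write_bed6(
            [(c.position, c.position + 1, f"TSS_{i}", c.pvalue, c.strand)
             for i, c in enumerate(tss_calls, 1)],
            outdir / "tss_calls.bed",
        )
        tio.write_bed6(
            [(c.position, c.position + 1, f"TPS_{i}", c.pvalue, c.strand)
             for i, c in enumerate(tps_calls, 1)],
            outdir / "tps_calls.bed",
        )
        tio.write_bed6(
            [(p.start, p.end, p.target_id or "intergenic", p.padj, p.strand)
             for p in sig_peaks],
            outdir / "peaks.bed",
        )
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
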