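"""Seeded generators for every input the pipeline consumes, with ground truth.

The generator emulates a desk-scale stand-in for a small archaeal chromosome:
an i.i.d. base sequence with a configurable GC fraction (default 0.37, the
low GC typical of *Sulfolobus*), non-overlapping gene models on both strands,
and Poisson count tracks.

* dRNA-seq: read-start tracks for the +TEX and -TEX libraries share a Poisson
  background; a planted TSS adds `depth` expected starts in -TEX and
  `ratio * depth` in +TEX at its exact position, and a planted TPS does the
  same with the libraries swapped.
* RIP-seq: mock coverage is Poisson(depth) everywhere; inside a planted peak
  the coIP mean is multiplied by 2**true_log2fc.
* Expression: per asRNA/mRNA pair, log2 fold changes across contrasts are
  drawn from a bivariate normal with the planted correlation; a protein table
  is coupled to the mRNA with an attenuation factor plus noise.

Counts are plain Poisson (the simplest model consistent with the detection
statistics); everything is deterministic under the seed, including the bytes
of every emitted file.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import Feature, GenomeAnnotation

DEFAULT_GENOME_LENGTH = 100_000
DEFAULT_N_GENES = 60
DEFAULT_GC = 0.37


def scaled_n_genes(genome_length: int) -> int:
    """Default gene count scaled to the genome (60 genes per 100 kb)."""
    return max(4, DEFAULT_N_GENES * genome_length // DEFAULT_GENOME_LENGTH)


@dataclass
class SyntheticTruth:
    """Ground truth for one synthetic study; round-trips through a TSV manifest."""

    genome_length: int
    seed: int
    gene_models: list[tuple[str, int, int, str]] = field(default_factory=list)
    planted_tss: list[tuple[int, str, float]] = field(default_factory=list)
    planted_tps: list[tuple[int, str, float]] = field(default_factory=list)
    planted_peaks: list[tuple[int, int, str, float]] = field(default_factory=list)
    planted_tts: list[tuple[int, str]] = field(default_factory=list)
    planted_transcripts: list[tuple[str, int, int, str, str]] = field(default_factory=list)
    pair_truth: list[tuple[str, str, float]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for pos, _, ratio in self.planted_tss + self.planted_tps:
            if not (0 <= pos < self.genome_length):
                raise ValueError(f"planted site at {pos} outside genome")
            if ratio <= 1:
                raise ValueError("enrichment/depletion ratio must be > 1")
        for start, end, _, _ in self.planted_peaks:
            if end - start < 1:
                raise ValueError("planted peak shorter than 1 nt")
            if not (0 <= start < end <= self.genome_length):
                raise ValueError("planted peak outside genome")
        for _, _, pcc in self.pair_truth:
            if not -1.0 <= pcc <= 1.0:
                raise ValueError("true_pcc must lie in [-1, 1]")

    def annotation(self) -> GenomeAnnotation:
        return GenomeAnnotation(
            [Feature(gid, "gene", s, e, strand) for gid, s, e, strand in self.gene_models]
        )

    # -- manifest round-trip -------------------------------------------------

    def write_manifest(self, path) -> None:
        rows = [
            {"record": "meta", "id": "genome_length", "start": self.genome_length,
             "end": "", "strand": "", "value": ""},
            {"record": "meta", "id": "seed", "start": self.seed, "end": "",
             "strand": "", "value": ""},
        ]
        for gid, s, e, strand in self.gene_models:
            rows.append({"record": "gene", "id": gid, "start": s, "end": e,
                         "strand": strand, "value": ""})
        for pos, strand, ratio in self.planted_tss:
            rows.append({"record": "tss", "id": "", "start": pos, "end": "",
                         "strand": strand, "value": ratio})
        for pos, strand, ratio in self.planted_tps:
            rows.append({"record": "tps", "id": "", "start": pos, "end": "",
                         "strand": strand, "value": ratio})
        for s, e, strand, lfc in self.planted_peaks:
            rows.append({"record": "peak", "id": "", "start": s, "end": e,
                         "strand": strand, "value": lfc})
        for pos, strand in self.planted_tts:
            rows.append({"record": "tts", "id": "", "start": pos, "end": "",
                         "strand": strand, "value": ""})
        for tid, s, e, strand, gene in self.planted_transcripts:
            rows.append({"record": "transcript", "id": tid, "start": s, "end": e,
                         "strand": strand, "value": gene})
        for mrna, asrna, pcc in self.pair_truth:
            rows.append({"record": "pair", "id": f"{mrna}|{asrna}", "start": "",
                         "end": "", "strand": "", "value": pcc})
        for msg in self.warnings:
            rows.append({"record": "warning", "id": "", "start": "", "end": "",
                         "strand": "", "value": msg})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def read_manifest(cls, path) -> "SyntheticTruth":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        meta = {r["id"]: r["start"] for _, r in df[df["record"] == "meta"].iterrows()}
        truth = cls(genome_length=int(meta["genome_length"]), seed=int(meta["seed"]))
        for _, r in df.iterrows():
            kind = r["record"]
            if kind == "gene":
                truth.gene_models.append(
                    (r["id"], int(r["start"]), int(r["end"]), r["strand"])
                )
            elif kind == "tss":
                truth.planted_tss.append((int(r["start"]), r["strand"], float(r["value"])))
            elif kind == "tps":
                truth.planted_tps.append((int(r["start"]), r["strand"], float(r["value"])))
            elif kind == "peak":
                truth.planted_peaks.append(
                    (int(r["start"]), int(r["end"]), r["strand"], float(r["value"]))
                )
            elif kind == "tts":
                truth.planted_tts.append((int(r["start"]), r["strand"]))
            elif kind == "transcript":
                truth.planted_transcripts.append(
                    (r["id"], int(r["start"]), int(r["end"]), r["strand"], r["value"])
                )
            elif kind == "pair":
                mrna, _, asrna = r["id"].partition("|")
                truth.pair_truth.append((mrna, asrna, float(r["value"])))
            elif kind == "warning":
                truth.warnings.append(r["value"])
        return truth


# ---------------------------------------------------------------------------
# Genome and gene models
# ---------------------------------------------------------------------------

def make_genome(
    length: int = DEFAULT_GENOME_LENGTH,
    gc_fraction: float = DEFAULT_GC,
    n_genes: int = DEFAULT_N_GENES,
    seed: int = 0,
    gene_length_range: tuple[int, int] = (300, 1200),
    min_gap: int = 60,
) -> tuple[str, list[tuple[str, int, int, str]]]:
    """Generate an i.i.d. base sequence and non-overlapping gene models.

    Bases are drawn independently with expected GC = ``gc_fraction`` (split
    evenly between G and C, and between A and T).  Genes are placed left to
    right on alternating random strands with at least ``min_gap`` nt between
    them; coordinates are linear (no circular wraparound).
    """
    if length < 1000:
        raise ValueError("genome length must be >= 1000")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = [
        (1 - gc_fraction) / 2,
        gc_fraction / 2,
        gc_fraction / 2,
        (1 - gc_fraction) / 2,
    ]
    seq = "".join(rng.choice(list("AGCT"), size=length, p=probs))

    gene_lengths = rng.integers(
        gene_length_range[0], gene_length_range[1] + 1, size=n_genes
    )
    needed = int(gene_lengths.sum()) + min_gap * (n_genes + 1)
    if needed > length:
        raise ValueError(
            f"genome of length {length} too small for {n_genes} genes "
            f"(need >= {needed} nt)"
        )
    slack = length - needed
    # distribute the slack into n_genes+1 random inter-gene gaps
    cuts = np.sort(rng.integers(0, slack + 1, size=n_genes))
    extra = np.diff(np.concatenate([[0], cuts, [slack]]))
    genes = []
    cursor = 0
    for i, glen in enumerate(gene_lengths):
        cursor += min_gap + int(extra[i])
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append((f"gene_{i + 1:04d}", cursor, cursor + int(glen), strand))
        cursor += int(glen)
    return seq, genes


def _sample_positions(
    rng: np.random.Generator,
    n: int,
    genome_length: int,
    occupied: list[int],
    min_sep: int = 30,
    margin: int = 25,
) -> list[int]:
    """Draw n positions keeping min_sep nt from each other and `occupied`."""
    taken = sorted(occupied)
    out: list[int] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 200 * n + 1000:
            raise ValueError("could not place requested sites; genome too crowded")
        pos = int(rng.integers(margin, genome_length - margin))
        if all(abs(pos - t) >= min_sep for t in taken):
            taken.append(pos)
            out.append(pos)
    return out


def make_truth(
    genome_length: int = DEFAULT_GENOME_LENGTH,
    gc_fraction: float = DEFAULT_GC,
    n_genes: int | None = None,
    n_tss: int | None = None,
    n_tps: int | None = None,
    n_peaks: int | None = None,
    n_asrna: int | None = None,
    enrichment_ratio: float = 5.0,
    depletion_ratio: float = 5.0,
    peak_width: int = 30,
    peak_log2fc: float = 2.0,
    pair_pccs: tuple[float, ...] = (-0.9, -0.5, 0.0, 0.5, 0.9),
    seed: int = 0,
) -> tuple[str, SyntheticTruth]:
    """Build a genome plus a full planted-truth manifest.

    Planted TSSs/TPSs are intergenic-ish single positions; each of the
    ``n_asrna`` antisense units plants an aTSS inside a gene on the opposite
    strand together with a TTS 80-350 nt downstream, defining an expected
    asRNA with exact coordinates, and assigns the unit a true expression
    correlation cycled from ``pair_pccs``.
    """
    scale = genome_length / DEFAULT_GENOME_LENGTH
    if n_genes is None:
        n_genes = scaled_n_genes(genome_length)
    if n_tss is None:
        n_tss = max(2, int(40 * scale))
    if n_tps is None:
        n_tps = max(2, int(40 * scale))
    if n_peaks is None:
        n_peaks = max(2, int(20 * scale))
    if n_asrna is None:
        n_asrna = max(2, int(20 * scale))
    rng = np.random.default_rng(seed)
    sequence, genes = make_genome(
        genome_length, gc_fraction, n_genes, seed=int(rng.integers(2**31))
    )
    truth = SyntheticTruth(genome_length=genome_length, seed=seed, gene_models=genes)

    occupied: list[int] = []
    tss_pos = _sample_positions(rng, n_tss, genome_length, occupied)
    occupied += tss_pos
    for pos in tss_pos:
        strand = "+" if rng.random() < 0.5 else "-"
        truth.planted_tss.append((pos, strand, enrichment_ratio))
    tps_pos = _sample_positions(rng, n_tps, genome_length, occupied)
    occupied += tps_pos
    for pos in tps_pos:
        strand = "+" if rng.random() < 0.5 else "-"
        truth.planted_tps.append((pos, strand, depletion_ratio))

    # antisense units: aTSS inside an opposite-strand gene + downstream TTS
    usable = [g for g in genes if g[2] - g[1] >= 500]
    rng.shuffle(usable)
    k = 0
    for gid, gstart, gend, gstrand in usable:
        if k >= n_asrna:
            break
        strand = "-" if gstrand == "+" else "+"
        tts_dist = int(rng.integers(80, 351))
        margin = 60
        if strand == "+":
            lo, hi = gstart + margin, gend - margin - tts_dist
            if hi <= lo:
                continue
            tss = int(rng.integers(lo, hi))
            tts = tss + tts_dist
            tstart, tend = tss, tts + 1
        else:
            lo, hi = gstart + margin + tts_dist, gend - margin
            if hi <= lo:
                continue
            tss = int(rng.integers(lo, hi))
            tts = tss - tts_dist
            tstart, tend = tts, tss + 1
        # avoid planting near existing sites and same-strand gene starts
        if any(abs(tss - p) < 30 for p in occupied):
            continue
        near_same_strand_start = any(
            g[3] == strand
            and (
                1 <= (g[1] - tss if strand == "+" else tss - (g[2] - 1)) <= 320
            )
            for g in genes
        )
        if near_same_strand_start:
            continue
        k += 1
        asrna_id = f"asRNA_planted_{k:03d}"
        truth.planted_tss.append((tss, strand, enrichment_ratio))
        truth.planted_tts.append((tts, strand))
        truth.planted_transcripts.append((asrna_id, tstart, tend, strand, gid))
        truth.pair_truth.append((gid, asrna_id, pair_pccs[(k - 1) % len(pair_pccs)]))
        occupied += [tss, tts]

    # RIP-seq peaks, non-overlapping, inside genes where possible
    peak_starts = _sample_positions(
        rng, n_peaks, genome_length - peak_width, occupied, min_sep=peak_width + 40
    )
    for s in peak_starts:
        strand = "+" if rng.random() < 0.5 else "-"
        truth.planted_peaks.append((s, s + peak_width, strand, peak_log2fc))

    # warn about same-strand planted 5'-end sites within the grouping gap
    sites = sorted(
        [(p, st) for p, st, _ in truth.planted_tss]
        + [(p, st) for p, st, _ in truth.planted_tps]
    )
    for (p1, s1), (p2, s2) in zip(sites, sites[1:]):
        if s1 == s2 and p2 - p1 <= 5:
            msg = f"planted sites at {p1} and {p2} ({s1}) within grouping gap"
            truth.warnings.append(msg)
            warnings.warn(msg)
    return sequence, truth


# ---------------------------------------------------------------------------
# Count-track simulators
# ---------------------------------------------------------------------------

def simulate_drna_tracks(
    truth: SyntheticTruth,
    depth: float = 10.0,
    background_rate: float = 0.5,
    n_reps: int = 2,
    seed: int = 0,
) -> dict[str, dict[str, list[np.ndarray]]]:
    """Simulate ±TEX read-start tracks: {library: {strand: [rep arrays]}}.

    Both libraries share a Poisson(background_rate) noise floor per position.
    At a planted TSS the -TEX mean gains `depth` and the +TEX mean gains
    `ratio * depth`; at a planted TPS the roles are swapped.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if background_rate < 0:
        raise ValueError("background_rate must be >= 0")
    rng = np.random.default_rng(seed)
    L = truth.genome_length
    lam = {
        lib: {s: np.full(L, float(background_rate)) for s in "+-"}
        for lib in ("+TEX", "-TEX")
    }
    for pos, strand, ratio in truth.planted_tss:
        lam["-TEX"][strand][pos] += depth
        lam["+TEX"][strand][pos] += ratio * depth
    for pos, strand, ratio in truth.planted_tps:
        lam["+TEX"][strand][pos] += depth
        lam["-TEX"][strand][pos] += ratio * depth
    return {
        lib: {
            strand: [rng.poisson(lam[lib][strand]) for _ in range(n_reps)]
            for strand in "+-"
        }
        for lib in ("+TEX", "-TEX")
    }


def simulate_ripseq(
    truth: SyntheticTruth,
    depth: float = 50.0,
    n_reps: int = 3,
    seed: int = 0,
) -> dict[str, dict[str, list[np.ndarray]]]:
    """Simulate coIP and mock coverage: {arm: {strand: [rep arrays]}}.

    Mock coverage is Poisson(depth) everywhere; inside planted peaks the coIP
    mean is depth * 2**true_log2fc, elsewhere the arms share the same mean.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    L = truth.genome_length
    lam_coip = {s: np.full(L, float(depth)) for s in "+-"}
    for start, end, strand, lfc in truth.planted_peaks:
        if end - start < 1:
            raise ValueError("planted peak shorter than 1 nt")
        lam_coip[strand][start:end] = depth * 2.0 ** lfc
    lam_mock = {s: np.full(L, float(depth)) for s in "+-"}
    return {
        "coip": {s: [rng.poisson(lam_coip[s]) for _ in range(n_reps)] for s in "+-"},
        "mock": {s: [rng.poisson(lam_mock[s]) for _ in range(n_reps)] for s in "+-"},
    }


# ---------------------------------------------------------------------------
# Expression simulator
# ---------------------------------------------------------------------------

def simulate_expression(
    pair_truth: list[tuple[str, str, float]],
    n_contrasts: int = 10,
    sigma: float = 1.0,
    seed: int = 0,
    effect_se: float = 0.3,
    protein_attenuation: float = 0.5,
    protein_sigma: float = 0.3,
    with_protein: bool = True,
) -> dict[str, pd.DataFrame]:
    """Draw correlated log2FC tables for mRNA/asRNA pairs (+ protein).

    Per pair and contrast, (mRNA, asRNA) log2FCs come from a bivariate normal
    with marginal sd ``sigma`` and the planted correlation.  The protein
    log2FC is ``protein_attenuation * mRNA`` plus Gaussian noise, emulating
    damped propagation of transcript changes to protein level.  P-values are
    generated consistently with the effect size as two-sided normal tails of
    lfc / effect_se.  Tables are long format: feature_id, contrast_id,
    log2fc, pvalue.
    """
    if n_contrasts < 3:
        raise ValueError("n_contrasts must be >= 3 (PCC undefined below that)")
    rng = np.random.default_rng(seed)
    contrasts = [f"contrast_{i + 1:02d}" for i in range(n_contrasts)]
    mrna_lfc: dict[str, np.ndarray] = {}
    rows = {"mrna": [], "asrna": [], "protein": []}

    def pvals(lfc: np.ndarray) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(lfc) / effect_se)

    for mrna_id, asrna_id, rho in pair_truth:
        if not -1.0 <= rho <= 1.0:
            raise ValueError("|true_pcc| must be <= 1")
        if mrna_id not in mrna_lfc:
            mrna_lfc[mrna_id] = sigma * rng.standard_normal(n_contrasts)
        x = mrna_lfc[mrna_id]
        eps = rng.standard_normal(n_contrasts)
        y = rho * x + sigma * np.sqrt(max(0.0, 1.0 - rho**2)) * eps
        for cid, v, p in zip(contrasts, y, pvals(y)):
            rows["asrna"].append(
                {"feature_id": asrna_id, "contrast_id": cid, "log2fc": float(v),
                 "pvalue": float(p)}
            )
    for mrna_id, x in mrna_lfc.items():
        for cid, v, p in zip(contrasts, x, pvals(x)):
            rows["mrna"].append(
                {"feature_id": mrna_id, "contrast_id": cid, "log2fc": float(v),
                 "pvalue": float(p)}
            )
        if with_protein:
            prot = protein_attenuation * x + protein_sigma * rng.standard_normal(
                n_contrasts
            )
            for cid, v, p in zip(contrasts, prot, pvals(prot)):
                rows["protein"].append(
                    {"feature_id": mrna_id, "contrast_id": cid, "log2fc": float(v),
                     "pvalue": float(p)}
                )
    out = {k: pd.DataFrame(v) for k, v in rows.items() if v}
    return out


def wide_lfc(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long fold-change table to a feature x contrast log2FC matrix."""
    return table.pivot(index="feature_id", columns="contrast_id", values="log2fc")
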