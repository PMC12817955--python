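"""RIP-seq interaction-site calling and characterization for RNA chaperones.

Co-immunoprecipitation (coIP) coverage of a tagged RNA-binding protein is
compared against a mock pulldown from an untagged strain.  Replicates are
library-size normalized to a common depth and averaged within each arm; a
coordinate-wise log2 fold change (coIP vs mock, with a pseudocount) then
defines candidate interaction sites as maximal runs of at least 10
consecutive positions with log2FC >= 1.  Candidate peaks are tested for
significance with a Welch test on log2 normalized per-peak replicate counts
(one-sided, since only enrichment is of interest), BH-adjusted; the emitted
set requires padj < 0.01 and mean log2FC >= 1.

Characterization covers target-transcript assignment, per-protein target-set
overlaps, positional preference along the transcript (5' quarter / internal
half / 3' quarter, by peak midpoint), and a GC-content comparison of peaks
against a genome-wide 50 nt / 25 nt-step sliding-window background
(two-sided Mann-Whitney U).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import Feature, GenomeAnnotation, StrandTrack

POSITIONAL_CLASSES = ("five_prime", "internal", "three_prime", "intergenic")


@dataclass
class InteractionPeak:
    """A candidate (or significant) RIP-seq interaction site."""

    start: int
    end: int
    strand: str
    mean_log2fc: float
    pvalue: float | None = None
    padj: float | None = None
    significant: bool = False
    target_id: str | None = None
    positional_class: str = "intergenic"
    gc_fraction: float | None = None

    def __len__(self) -> int:
        return self.end - self.start

    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


def _as_arrays(reps) -> list[np.ndarray]:
    if isinstance(reps, (np.ndarray, StrandTrack)):
        reps = [reps]
    return [
        np.asarray(r.counts if isinstance(r, StrandTrack) else r, dtype=float)
        for r in reps
    ]


def normalize_replicates(coip_reps, mock_reps) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Scale every replicate to the mean library size across both arms."""
    coip = _as_arrays(coip_reps)
    mock = _as_arrays(mock_reps)
    sizes = [a.sum() for a in coip + mock]
    if any(s <= 0 for s in sizes):
        raise ValueError("replicate with zero library size")
    target = float(np.mean(sizes))
    coip = [a * (target / a.sum()) for a in coip]
    mock = [a * (target / a.sum()) for a in mock]
    return coip, mock


def log2fc_track(coip_reps, mock_reps, pseudocount: float = 1.0) -> np.ndarray:
    """Coordinate-wise log2((coip + pc) / (mock + pc)) on normalized coverage.

    Each replicate is normalized to the mean library size, then averaged
    within its arm, yielding one coverage track per arm before the ratio.
    """
    coip, mock = normalize_replicates(coip_reps, mock_reps)
    coip_mean = np.mean(coip, axis=0)
    mock_mean = np.mean(mock, axis=0)
    return np.log2((coip_mean + pseudocount) / (mock_mean + pseudocount))


def find_peaks(
    log2fc_array: np.ndarray, min_run: int = 10, threshold: float = 1.0
) -> list[tuple[int, int]]:
    """Maximal runs of positions with value >= threshold, length >= min_run."""
    arr = np.asarray(log2fc_array)
    mask = arr >= threshold
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    return [(int(s), int(e)) for s, e in zip(starts, ends) if e - s >= min_run]


def test_peaks(
    peaks: Sequence[tuple[int, int]],
    coip_reps,
    mock_reps,
    strand: str = "+",
    pseudocount: float = 1.0,
    min_lfc: float = 1.0,
    max_padj: float = 0.01,
) -> list[InteractionPeak]:
    """Attach p-values (Welch, one-sided) and BH-adjusted q-values to peaks.

    Per-peak replicate read sums are library-size normalized, log2(x + 1)
    transformed and compared coIP vs mock.  A peak is flagged significant
    when padj < max_padj and its mean log2FC >= min_lfc.  With fewer than two
    replicates per arm no p-value can be computed and peaks are left
    unflagged.
    """
    peaks = list(peaks)
    if any(e - s < 1 for s, e in peaks):
        raise ValueError("zero-width peak")
    if not peaks:
        return []
    coip, mock = normalize_replicates(coip_reps, mock_reps)
    lfc = log2fc_track(coip_reps, mock_reps, pseudocount=pseudocount)

    can_test = len(coip) >= 2 and len(mock) >= 2
    results: list[InteractionPeak] = []
    pvals: list[float] = []
    for s, e in peaks:
        mean_lfc = float(np.mean(lfc[s:e]))
        peak = InteractionPeak(start=s, end=e, strand=strand, mean_log2fc=mean_lfc)
        if can_test:
            a = np.log2(np.array([r[s:e].sum() for r in coip]) + 1.0)
            b = np.log2(np.array([r[s:e].sum() for r in mock]) + 1.0)
            t = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
            peak.pvalue = float(t.pvalue) if np.isfinite(t.pvalue) else 1.0
            pvals.append(peak.pvalue)
        results.append(peak)
    if can_test and pvals:
        _, padj, _, _ = multipletests(pvals, method="fdr_bh")
        for peak, q in zip(results, padj):
            peak.padj = float(q)
            peak.significant = peak.padj < max_padj and peak.mean_log2fc >= min_lfc
    return results


def significant_peaks(peaks: Iterable[InteractionPeak]) -> list[InteractionPeak]:
    return [p for p in peaks if p.significant]


def assign_targets(
    peaks: Iterable[InteractionPeak],
    annotation: GenomeAnnotation,
    types: tuple[str, ...] = ("gene", "asRNA", "sRNA", "smORF"),
) -> list[InteractionPeak]:
    """Assign each peak to the same-strand transcript with maximal overlap.

    Ties resolve to the larger overlap fraction of the transcript, then the
    lexicographically smallest id.  Peaks overlapping nothing stay intergenic.
    """
    transcripts = annotation.of_type(*types)
    out = []
    for peak in peaks:
        best_key = None
        best_id = None
        for f in transcripts:
            if f.strand != peak.strand:
                continue
            ov = f.overlap(peak.start, peak.end)
            if ov == 0:
                continue
            key = (ov, ov / len(f))
            if best_key is None or key > best_key or (key == best_key and f.id < best_id):
                best_key, best_id = key, f.id
        peak.target_id = best_id
        if best_id is None:
            peak.positional_class = "intergenic"
        out.append(peak)
    return out


def target_set(peaks: Iterable[InteractionPeak]) -> set[str]:
    """Unique target ids of the significant peaks of one protein."""
    return {p.target_id for p in peaks if p.significant and p.target_id is not None}


def overlap_sets(targets_a: set[str], targets_b: set[str]) -> tuple[int, int, int]:
    """Counts (only_a, only_b, both); they sum to the size of the union."""
    both = targets_a & targets_b
    return (len(targets_a - both), len(targets_b - both), len(both))


def positional_class(peak: InteractionPeak, transcript: Feature) -> str:
    """Classify a peak by its midpoint fraction along the transcript 5'->3'.

    [0, 0.25) -> five_prime, [0.25, 0.75) -> internal, [0.75, 1] -> three_prime.
    """
    length = len(transcript)
    if length == 0:
        raise ValueError("zero-length transcript")
    mid = peak.midpoint()
    if transcript.strand == "+":
        frac = (mid - transcript.start) / length
    else:
        frac = (transcript.end - mid) / length
    frac = min(max(frac, 0.0), 1.0)
    if frac < 0.25:
        return "five_prime"
    if frac < 0.75:
        return "internal"
    return "three_prime"


def classify_peak_positions(
    peaks: Iterable[InteractionPeak], annotation: GenomeAnnotation
) -> list[InteractionPeak]:
    out = []
    for peak in peaks:
        if peak.target_id is not None:
            peak.positional_class = positional_class(peak, annotation.get(peak.target_id))
        out.append(peak)
    return out


def gc_fraction(seq: str) -> float:
    seq = seq.upper()
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def sliding_gc(genome: str, window: int = 50, step: int = 25) -> np.ndarray:
    """GC fraction of sliding windows (start 0, given step, full windows only).

    The number of windows is floor((L - window) / step) + 1.
    """
    L = len(genome)
    if L < window:
        raise ValueError(f"genome shorter than one window ({L} < {window})")
    n = (L - window) // step + 1
    return np.array(
        [gc_fraction(genome[i * step:i * step + window]) for i in range(n)]
    )


@dataclass
class GcTestResult:
    peak_gc: np.ndarray
    background_gc: np.ndarray
    u_statistic: float
    pvalue: float

    @property
    def significant(self) -> bool:
        return self.pvalue < 0.05


def gc_background_test(
    peaks: Iterable[InteractionPeak],
    genome: str,
    window: int = 50,
    step: int = 25,
) -> GcTestResult:
    """Two-sided Mann-Whitney U of peak GC vs sliding-window background GC.

    Also stores each peak's GC fraction on the peak record.
    """
    peaks = list(peaks)
    if not peaks:
        raise ValueError("no peaks to test")
    background = sliding_gc(genome, window=window, step=step)
    peak_gc = []
    for p in peaks:
        p.gc_fraction = gc_fraction(genome[p.start:p.end])
        peak_gc.append(p.gc_fraction)
    peak_gc = np.array(peak_gc)
    u, pval = stats.mannwhitneyu(peak_gc, background, alternative="two-sided")
    return GcTestResult(peak_gc, background, float(u), float(pval))
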