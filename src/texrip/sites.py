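"""Position-wise detection of primary and processed 5' ends from dRNA-seq.

dRNA-seq compares two libraries per strand: one treated with terminator
exonuclease (+TEX), which degrades 5'-monophosphorylated (processed) RNAs and
therefore enriches primary transcripts, and an untreated (-TEX) control.  A
transcription start site (TSS) is a position whose read starts are
significantly enriched in +TEX; a transcript processing site (TPS) is the
mirror image — a 5' end significantly depleted in +TEX — and is detected by
inverting the library roles.

The per-position decision is an exact conditional binomial rate-ratio test:
conditioned on the total number of read starts n = k_a + k_b at a position,
k_a ~ Binomial(n, s_a / (s_a + s_b)) under the null hypothesis of equal rates,
where s_a and s_b are the library sizes.  The one-sided p-value P(X >= k_a)
is exact and parameter-free.

The downstream filter cascade uses a normalized "score" (read starts in the
enriched library per 1e7 library counts) and "delta" (difference of the
normalized counts of the two libraries on the same scale); both are plain
config thresholds and can be recalibrated.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .io import Feature, GenomeAnnotation, StrandTrack

TSS_CLASSES = ("pTSS", "UTR", "iTSS", "aTSS", "oTSS")

#: normalization scale for score/delta: read starts per 1e7 library counts
SCORE_SCALE = 1e7


@dataclass
class SiteCall:
    """One called TSS or TPS."""

    position: int
    strand: str
    k_enriched: int
    k_depleted: int
    score: float
    delta: float
    pvalue: float
    site_type: str  # "TSS" or "TPS"
    tss_class: str = "n/a"


def site_test(k_a: int, k_b: int, s_a: float, s_b: float) -> float:
    """One-sided exact test for enrichment of library a over library b.

    Returns P(X >= k_a) with X ~ Binomial(k_a + k_b, s_a / (s_a + s_b)).
    With no evidence at all (k_a = k_b = 0) the p-value is 1.
    """
    if k_a < 0 or k_b < 0:
        raise ValueError("read-start counts must be non-negative")
    if s_a <= 0 or s_b <= 0:
        raise ValueError("library sizes must be positive")
    n = k_a + k_b
    if n == 0:
        return 1.0
    p0 = s_a / (s_a + s_b)
    return float(stats.binom.sf(k_a - 1, n, p0))


def _sum_replicates(tracks) -> np.ndarray:
    """Accept an array, a StrandTrack, or a sequence of either; sum counts."""
    if isinstance(tracks, StrandTrack):
        return np.asarray(tracks.counts, dtype=float)
    if isinstance(tracks, np.ndarray):
        return tracks.astype(float)
    arrays = [
        np.asarray(t.counts if isinstance(t, StrandTrack) else t, dtype=float)
        for t in tracks
    ]
    lengths = {a.shape[0] for a in arrays}
    if len(lengths) != 1:
        raise ValueError(f"replicate tracks have mismatched lengths: {sorted(lengths)}")
    return np.sum(arrays, axis=0)


def group_positions(positions: Sequence[int], gap: int) -> list[list[int]]:
    """Cluster sorted candidate positions; neighbours within `gap` nt merge."""
    groups: list[list[int]] = []
    for pos in sorted(positions):
        if groups and pos - groups[-1][-1] <= gap:
            groups[-1].append(pos)
        else:
            groups.append([pos])
    return groups


def call_sites(
    track_enriched,
    track_depleted,
    strand: str = "+",
    min_reads: int = 10,
    alpha: float = 1e-9,
    group_gap: int = 5,
    site_type: str = "TSS",
) -> list[SiteCall]:
    """Call significantly enriched 5'-end positions on one strand.

    Replicates (if given as a list of tracks) are summed per library before
    testing.  Positions with at least `min_reads` starts in the enriched
    library and one-sided p < `alpha` become candidates; candidates within
    `group_gap` nt of each other merge into one group whose representative is
    the position with the maximal enriched count (ties resolved to the most
    5' position on the strand).
    """
    enriched = _sum_replicates(track_enriched)
    depleted = _sum_replicates(track_depleted)
    if enriched.shape != depleted.shape:
        raise ValueError(
            f"track length mismatch: {enriched.shape[0]} vs {depleted.shape[0]}"
        )
    s_enr = float(enriched.sum())
    s_dep = float(depleted.sum())
    if s_enr <= 0 or s_dep <= 0:
        return []
    p0 = s_enr / (s_enr + s_dep)

    candidate_pos = np.flatnonzero(enriched >= min_reads)
    if candidate_pos.size == 0:
        return []
    k_a = enriched[candidate_pos]
    k_b = depleted[candidate_pos]
    pvals = stats.binom.sf(k_a - 1, k_a + k_b, p0)
    keep = pvals < alpha
    candidate_pos = candidate_pos[keep]
    pvals = pvals[keep]
    pval_at = dict(zip(candidate_pos.tolist(), pvals.tolist()))

    calls: list[SiteCall] = []
    for group in group_positions(candidate_pos.tolist(), group_gap):
        counts = [enriched[p] for p in group]
        best = max(counts)
        tied = [p for p, c in zip(group, counts) if c == best]
        # most 5' position: smallest coordinate on +, largest on -
        rep = min(tied) if strand == "+" else max(tied)
        k_e = int(enriched[rep])
        k_d = int(depleted[rep])
        score = k_e / s_enr * SCORE_SCALE
        delta = score - k_d / s_dep * SCORE_SCALE
        calls.append(
            SiteCall(
                position=int(rep),
                strand=strand,
                k_enriched=k_e,
                k_depleted=k_d,
                score=score,
                delta=delta,
                pvalue=pval_at[rep],
                site_type=site_type,
            )
        )
    return calls


def call_tps(track_plus_tex, track_minus_tex, **kwargs) -> list[SiteCall]:
    """Call transcript processing sites by inverting the library roles.

    Identical to ``call_sites`` with enriched := -TEX and depleted := +TEX;
    the resulting calls carry ``site_type="TPS"``.
    """
    kwargs["site_type"] = "TPS"
    return call_sites(track_minus_tex, track_plus_tex, **kwargs)


def apply_site_filters(
    calls: Iterable[SiteCall],
    min_score: float = 600.0,
    min_delta: float = 10.0,
    max_p: float = 0.05,
) -> list[SiteCall]:
    """Filter calls on score >= min_score, delta >= min_delta, p <= max_p.

    All three thresholds are inclusive.
    """
    return [
        c
        for c in calls
        if c.score >= min_score and c.delta >= min_delta and c.pvalue <= max_p
    ]


def classify_tss(
    calls: Iterable[SiteCall],
    annotation: GenomeAnnotation,
    genome_length: int,
    upstream_window: int = 300,
    antisense_flank: int = 100,
) -> list[SiteCall]:
    """Assign one of five positional classes to each TSS call.

    pTSS: within `upstream_window` nt upstream of a same-strand gene start and
    the closest such call to that start; UTR: within the window but not the
    closest; iTSS: inside a same-strand gene body; aTSS: inside an
    opposite-strand gene or within `antisense_flank` nt of its boundaries;
    oTSS: none of the above.  A call matching several rules takes the first
    class in the precedence order pTSS > UTR > iTSS > aTSS > oTSS.
    """
    calls = list(calls)
    for c in calls:
        if not (0 <= c.position < genome_length):
            raise ValueError(f"call at {c.position} beyond genome bounds")

    genes = annotation.of_type("gene")

    def upstream_distance(call: SiteCall, gene: Feature) -> int | None:
        """Distance from call to the gene's 5' end, if strictly upstream."""
        if call.strand != gene.strand:
            return None
        if gene.strand == "+":
            d = gene.start - call.position
        else:
            d = call.position - (gene.end - 1)
        return d if 1 <= d <= upstream_window else None

    primary: set[int] = set()   # indices of calls that are pTSS
    in_window: set[int] = set()  # indices within some gene's upstream window
    for gene in genes:
        dists = [
            (upstream_distance(c, gene), i)
            for i, c in enumerate(calls)
        ]
        dists = [(d, i) for d, i in dists if d is not None]
        if not dists:
            continue
        in_window.update(i for _, i in dists)
        primary.add(min(dists)[1])

    out: list[SiteCall] = []
    for i, c in enumerate(calls):
        if i in primary:
            cls = "pTSS"
        elif i in in_window:
            cls = "UTR"
        elif any(
            g.strand == c.strand and g.start <= c.position < g.end for g in genes
        ):
            cls = "iTSS"
        elif any(
            g.strand != c.strand
            and g.start - antisense_flank <= c.position < g.end + antisense_flank
            for g in genes
        ):
            cls = "aTSS"
        else:
            cls = "oTSS"
        out.append(replace(c, tss_class=cls))
    return out


# full IUPAC complement (degenerate letters map to their complement classes)
_COMPLEMENT = str.maketrans(
    "ACGTURYSWKMBDHVNacgturyswkmbdhvn",
    "TGCAAYRSWMKVHDBNtgcaayrswmkvhdbn",
)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Flank:
    """Sequence context around one site (site at the center index `flank`)."""

    position: int
    strand: str
    seq: str
    truncated: bool


def extract_flanks(calls: Iterable[SiteCall], genome: str, flank: int = 10) -> list[Flank]:
    """Extract the 2*flank+1 nt sequence centered on each site.

    Minus-strand sites return the reverse complement, so the returned
    sequence always reads 5'->3' on the transcript's strand.  Sites closer
    than `flank` to a genome edge yield a truncated sequence with a flag.
    """
    out = []
    L = len(genome)
    for c in calls:
        lo = c.position - flank
        hi = c.position + flank + 1
        truncated = lo < 0 or hi > L
        seq = genome[max(0, lo):min(L, hi)]
        if c.strand == "-":
            seq = reverse_complement(seq)
        out.append(Flank(c.position, c.strand, seq, truncated))
    return out
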