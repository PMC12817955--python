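"""Annotation of novel transcripts from filtered TSS calls plus Term-seq TTSs.

An orphan (oTSS) or antisense (aTSS) transcription start is turned into a
transcript candidate by searching for a transcription termination site (TTS)
within a 400 bp window downstream of the TSS; the nearest downstream TTS on
the same strand defines the 3' boundary.  Antisense starts yield asRNAs (with
their cognate sense genes recorded), orphan starts yield sRNAs, and candidates
harbouring an open reading frame of 10-49 amino acids are upgraded to smORFs
(small protein-coding genes, defined as encoding proteins shorter than 50 aa).

The module also extracts promoter regions for logo analysis, scans sequences
with IUPAC degenerate consensus motifs (including the four processing-site
motifs reported for S. acidocaldarius), and counts processing sites per
transcript.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .io import Feature, GenomeAnnotation
from .sites import SiteCall, reverse_complement

logger = logging.getLogger(__name__)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class IupacMotif:
    """A degenerate consensus motif (U is treated as T)."""

    name: str
    consensus: str
    strandedness: str = "both"  # "both" or "sense"

    def __post_init__(self) -> None:
        self.consensus = self.consensus.upper().replace("U", "T")
        bad = set(self.consensus) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC letters in {self.name}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.consensus)

    def regex(self) -> re.Pattern:
        return re.compile("".join(f"[{IUPAC[ch]}]" for ch in self.consensus))


#: The four processing-site consensus motifs reported for S. acidocaldarius.
PROCESSING_MOTIFS = {
    "Motif-1": IupacMotif("Motif-1", "AACGACAAGAAACUAAAAC"),
    "Motif-2": IupacMotif("Motif-2", "HHNUUAHAHUURUDDVDNY"),
    "Motif-3": IupacMotif("Motif-3", "DNYHAAGGAYDHDG"),
    "Motif-4": IupacMotif("Motif-4", "DDNWDNHBYWRGGACWR"),
}


@dataclass
class TranscriptCandidate:
    """A novel asRNA/sRNA/smORF candidate (internal coordinates)."""

    id: str
    start: int
    end: int
    strand: str
    source_tss: int
    matched_tts: int
    category: str  # asRNA | sRNA | smORF
    cognate_gene_ids: list[str] = field(default_factory=list)
    orf: tuple[int, int, int] | None = None  # transcript-relative (start, end, aa_length)
    expression_validated: bool = False

    def __len__(self) -> int:
        return self.end - self.start


def match_tts(
    tss: SiteCall,
    tts_positions: Iterable[tuple[int, str]],
    window: int = 400,
    transcript_id: str | None = None,
) -> TranscriptCandidate | None:
    """Pair one oTSS/aTSS call with the nearest downstream TTS.

    Candidate TTSs are same-strand positions within (tss, tss + window]
    measured 5'->3' on the call's strand; if none exists, no transcript is
    produced.  The emitted interval spans TSS and TTS inclusively, so its
    length is distance + 1 (at most 401 nt).
    """
    pos = tss.position
    best: int | None = None
    best_dist = window + 1
    for t, strand in tts_positions:
        if strand != tss.strand:
            continue
        dist = t - pos if tss.strand == "+" else pos - t
        if dist <= 0:
            continue  # upstream or coincident TTS: not a candidate
        if dist <= window and dist < best_dist:
            best, best_dist = t, dist
    if best is None:
        return None
    start, end = (pos, best + 1) if tss.strand == "+" else (best, pos + 1)
    category = "asRNA" if tss.tss_class == "aTSS" else "sRNA"
    return TranscriptCandidate(
        id=transcript_id or f"{category}_{pos}_{tss.strand}",
        start=start,
        end=end,
        strand=tss.strand,
        source_tss=pos,
        matched_tts=best,
        category=category,
    )


def transcript_sequence(candidate: TranscriptCandidate, genome: str) -> str:
    seq = genome[candidate.start:candidate.end]
    return reverse_complement(seq) if candidate.strand == "-" else seq


def find_orfs(
    candidate: TranscriptCandidate,
    genome: str,
    min_aa: int = 10,
    max_aa: int = 49,
    starts: Sequence[str] = START_CODONS,
) -> TranscriptCandidate:
    """Find the longest complete ORF inside the transcript; upgrade to smORF.

    An ORF is a listed start codon followed by an in-frame stop codon fully
    inside the transcript.  aa_length counts the codons strictly between the
    start and the stop codons.  If min_aa <= aa_length <= max_aa the
    candidate's category becomes smORF; otherwise it is returned unchanged.
    """
    seq = transcript_sequence(candidate, genome)
    best: tuple[int, int] | None = None  # (start_offset, stop_end_offset)
    for i in range(len(seq) - 5):
        if seq[i:i + 3] not in starts:
            continue
        for j in range(i + 3, len(seq) - 2, 3):
            if seq[j:j + 3] in STOP_CODONS:
                if best is None or (j + 3 - i) > (best[1] - best[0]):
                    best = (i, j + 3)
                break
    if best is None:
        return candidate
    aa_length = (best[1] - best[0]) // 3 - 2  # codons between start and stop
    orf = (best[0], best[1], aa_length)
    if min_aa <= aa_length <= max_aa:
        candidate.category = "smORF"
        candidate.orf = orf
    else:
        candidate.orf = orf
    return candidate


def validate_expression(
    candidates: Iterable[TranscriptCandidate],
    tpm_matrix: pd.DataFrame,
    min_tpm: float = 1.0,
    min_conditions: int = 1,
) -> list[TranscriptCandidate]:
    """Flag candidates expressed at >= min_tpm TPM in >= min_conditions.

    Only validated candidates enter the final annotation.  A candidate absent
    from the matrix is treated as unvalidated (with a logged warning).
    """
    out = []
    for c in candidates:
        if c.id not in tpm_matrix.index:
            logger.warning("candidate %s missing from TPM matrix; not validated", c.id)
            c.expression_validated = False
        else:
            row = tpm_matrix.loc[c.id]
            c.expression_validated = int((row >= min_tpm).sum()) >= min_conditions
        out.append(c)
    return out


@dataclass
class PromoterSeq:
    id: str
    seq: str
    truncated: bool


def extract_promoters(
    items: Iterable,
    genome: str,
    upstream: int = 50,
) -> list[PromoterSeq]:
    """Extract the `upstream` nt immediately 5' of each TSS (strand-aware).

    Accepts SiteCalls or TranscriptCandidates; the TSS base itself is not
    included.  Minus-strand promoters are reverse-complemented so that the
    returned sequence reads 5'->3' with the TSS adjacent to its 3' end.
    """
    if upstream < 1:
        raise ValueError("upstream must be >= 1")
    L = len(genome)
    out = []
    for item in items:
        if isinstance(item, TranscriptCandidate):
            pos, strand, name = item.source_tss, item.strand, item.id
        else:
            pos, strand = item.position, item.strand
            name = f"TSS_{pos}_{strand}"
        if strand == "+":
            lo, hi = pos - upstream, pos
            truncated = lo < 0
            seq = genome[max(0, lo):hi]
        else:
            lo, hi = pos + 1, pos + 1 + upstream
            truncated = hi > L
            seq = reverse_complement(genome[lo:min(L, hi)])
        out.append(PromoterSeq(name, seq, truncated))
    return out


@dataclass
class MotifHit:
    seq_id: str
    offset: int  # 0-based offset of the match start in the scanned sequence
    strand: str  # "+" = as given, "-" = hit on the reverse complement


def scan_motif(sequences: dict[str, str], motif: IupacMotif) -> list[MotifHit]:
    """Scan sequences for a degenerate consensus; overlapping hits allowed.

    Minus-strand hits (when motif.strandedness == "both") are found by
    matching the reverse complement of the consensus and are reported at
    their offset on the given (plus) sequence.
    """
    pattern = motif.regex()
    patterns = [("+", pattern)]
    if motif.strandedness == "both":
        rc = IupacMotif(motif.name, reverse_complement(motif.consensus))
        patterns.append(("-", rc.regex()))
    hits = []
    for seq_id, seq in sequences.items():
        seq = seq.upper().replace("U", "T")
        for strand, pat in patterns:
            for i in range(len(seq) - len(motif) + 1):
                if pat.match(seq, i, i + len(motif)):
                    hits.append(MotifHit(seq_id, i, strand))
    return hits


def motif_hit_counts(
    sequences_by_category: dict[str, dict[str, str]],
    motifs: dict[str, IupacMotif] = PROCESSING_MOTIFS,
) -> pd.DataFrame:
    """Count motif hits per feature category (e.g. ncRNA vs mRNA flanks)."""
    rows = []
    for motif_name, motif in motifs.items():
        for category, seqs in sequences_by_category.items():
            rows.append(
                {
                    "motif": motif_name,
                    "category": category,
                    "n_hits": len(scan_motif(seqs, motif)),
                    "n_sequences": len(seqs),
                }
            )
    return pd.DataFrame(rows)


def count_tps_per_transcript(
    tps_calls: Iterable[SiteCall],
    annotation: GenomeAnnotation,
    types: tuple[str, ...] = ("gene", "asRNA", "sRNA", "smORF"),
) -> pd.Series:
    """Count same-strand TPS positions inside each annotated transcript."""
    counts = {}
    calls = list(tps_calls)
    for f in annotation.of_type(*types):
        counts[f.id] = sum(
            1
            for c in calls
            if c.strand == f.strand and f.start <= c.position < f.end
        )
    return pd.Series(counts, dtype=int, name="n_tps")


def merge_with_curated(
    novel: Iterable[TranscriptCandidate],
    curated: GenomeAnnotation,
    min_reciprocal_overlap: float = 0.9,
) -> list[Feature]:
    """Merge novel candidates with a curated set, collapsing duplicates.

    A novel candidate with >= `min_reciprocal_overlap` reciprocal overlap to
    a same-strand curated feature is dropped in favour of the curated entry.
    The merged list never contains two features with identical
    (start, end, strand).
    """
    merged: list[Feature] = list(curated.features)
    seen = {(f.start, f.end, f.strand) for f in merged}
    for c in novel:
        duplicate = False
        for f in curated.features:
            if f.strand != c.strand:
                continue
            ov = f.overlap(c.start, c.end)
            if ov >= min_reciprocal_overlap * len(f) and ov >= min_reciprocal_overlap * (c.end - c.start):
                duplicate = True
                break
        key = (c.start, c.end, c.strand)
        if duplicate or key in seen:
            continue
        seen.add(key)
        merged.append(
            Feature(
                id=c.id,
                type=c.category,
                start=c.start,
                end=c.end,
                strand=c.strand,
                attributes={"source_tss": str(c.source_tss), "matched_tts": str(c.matched_tts)},
            )
        )
    return merged


def annotate_transcripts(
    calls: Iterable[SiteCall],
    tts_positions: Iterable[tuple[int, str]],
    genome: str,
    annotation: GenomeAnnotation,
    tpm_matrix: pd.DataFrame | None = None,
    window: int = 400,
    min_aa: int = 10,
    max_aa: int = 49,
) -> list[TranscriptCandidate]:
    """Full annotation pass: oTSS/aTSS -> TTS match -> ORF check -> cognates.

    Expression validation runs only when a TPM matrix is supplied; without
    one, all candidates are kept unflagged.
    """
    tts_list = list(tts_positions)
    genes = annotation.of_type("gene")
    candidates: list[TranscriptCandidate] = []
    n_as = n_s = 0
    for call in calls:
        if call.tss_class not in ("oTSS", "aTSS"):
            continue
        cand = match_tts(call, tts_list, window=window)
        if cand is None:
            continue
        if cand.category == "asRNA":
            n_as += 1
            cand.id = f"asRNA_{n_as}"
            cand.cognate_gene_ids = [
                g.id
                for g in genes
                if g.strand != cand.strand and g.overlap(cand.start, cand.end) > 0
            ]
        else:
            n_s += 1
            cand.id = f"sRNA_{n_s}"
        cand = find_orfs(cand, genome, min_aa=min_aa, max_aa=max_aa)
        candidates.append(cand)
    if tpm_matrix is not None:
        candidates = validate_expression(candidates, tpm_matrix)
    return candidates
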