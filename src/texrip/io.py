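"""Readers and writers for the on-disk formats used throughout the pipeline.

Internal coordinates are 0-based, half-open and strand-explicit everywhere in
this package.  GFF3 uses 1-based inclusive coordinates; the conversion between
the two conventions happens in this module and nowhere else, so any off-by-one
bug has exactly one place to live.

Bedgraph files carry raw integer read-start counts (or coverage); library-size
normalization is always performed downstream so that the files on disk stay
auditable against the raw data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FEATURE_TYPES = {"gene", "asRNA", "sRNA", "smORF", "TSS", "TPS", "peak"}
STRANDS = {"+", "-"}


@dataclass
class Feature:
    """A stranded genomic feature in internal (0-based, half-open) coordinates."""

    id: str
    type: str
    start: int
    end: int
    strand: str
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand symbol {self.strand!r} for feature {self.id!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.id!r}: invalid interval [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, start: int, end: int) -> int:
        """Length of the overlap with [start, end) in nt (0 if disjoint)."""
        return max(0, min(self.end, end) - max(self.start, start))


@dataclass
class GenomeAnnotation:
    """A set of features with unique ids (one genome, one coordinate system)."""

    features: list[Feature]

    def __post_init__(self) -> None:
        ids = [f.id for f in self.features]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate feature ids: {dup[:5]}")

    def __iter__(self):
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def of_type(self, *types: str) -> list[Feature]:
        return [f for f in self.features if f.type in types]

    def get(self, feature_id: str) -> Feature:
        for f in self.features:
            if f.id == feature_id:
                return f
        raise KeyError(feature_id)


@dataclass
class StrandTrack:
    """Dense per-position counts for one strand of one library/replicate."""

    counts: np.ndarray
    strand: str = "+"
    library: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any():
            raise ValueError("track contains negative counts")

    @property
    def library_size(self) -> float:
        return float(self.counts.sum())


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# bedgraph (4-column, 0-based half-open intervals)
# ---------------------------------------------------------------------------

def read_bedgraph(path, genome_length: int) -> np.ndarray:
    """Read a 4-column bedgraph into a dense per-position array.

    Gaps are filled with 0; overlapping intervals are an error (a well-formed
    single-track bedgraph partitions its covered positions).
    """
    counts = np.zeros(genome_length, dtype=float)
    occupied = np.zeros(genome_length, dtype=bool)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}: malformed bedgraph line {lineno}: {line!r}")
            try:
                start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed bedgraph line {lineno}: {line!r}"
                ) from exc
            if start < 0 or end > genome_length or start >= end:
                raise ValueError(
                    f"{path}: line {lineno}: interval [{start}, {end}) outside "
                    f"genome of length {genome_length}"
                )
            if occupied[start:end].any():
                raise ValueError(f"{path}: line {lineno}: overlapping interval")
            occupied[start:end] = True
            counts[start:end] = value
    return counts


def write_bedgraph(counts: np.ndarray, path, chrom: str = "genome") -> None:
    """Write a dense array as run-length-encoded bedgraph (zero runs omitted)."""
    counts = np.asarray(counts)
    with open(path, "w") as fh:
        if counts.size == 0:
            return
        boundaries = np.flatnonzero(np.diff(counts)) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [counts.size]])
        for s, e in zip(starts, ends):
            v = counts[s]
            if v == 0:
                continue
            if float(v).is_integer():
                fh.write(f"{chrom}\t{s}\t{e}\t{int(v)}\n")
            else:
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


# ---------------------------------------------------------------------------
# GFF3 (1-based, inclusive on disk; converted here and only here)
# ---------------------------------------------------------------------------

_GFF_COLUMNS = 9


def write_gff3(annotation: GenomeAnnotation, path, chrom: str = "genome",
               source: str = "texrip") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in annotation:
            attrs = ";".join(
                [f"ID={f.id}"] + [f"{k}={v}" for k, v in f.attributes.items()]
            )
            fh.write(
                "\t".join(
                    [
                        chrom,
                        source,
                        f.type,
                        str(f.start + 1),  # internal 0-based -> GFF3 1-based
                        str(f.end),        # half-open end == inclusive end + 1
                        ".",
                        f.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gff3(path) -> GenomeAnnotation:
    features: list[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != _GFF_COLUMNS:
                raise ValueError(f"{path}: line {lineno}: expected 9 GFF3 columns")
            _, _, ftype, start1, end1, _, strand, _, attr_field = parts
            if strand not in STRANDS:
                raise ValueError(f"{path}: line {lineno}: unknown strand {strand!r}")
            start1, end1 = int(start1), int(end1)
            if end1 < start1:
                raise ValueError(f"{path}: line {lineno}: end < start")
            attributes = {}
            for item in attr_field.split(";"):
                if not item:
                    continue
                key, _, value = item.partition("=")
                attributes[key] = value
            fid = attributes.pop("ID", f"feature_{lineno}")
            features.append(
                Feature(
                    id=fid,
                    type=ftype,
                    start=start1 - 1,  # GFF3 1-based -> internal 0-based
                    end=end1,
                    strand=strand,
                    attributes=attributes,
                )
            )
    return GenomeAnnotation(features)


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------

def bed_score(pvalue: float) -> int:
    """Conventional BED score: round(-10*log10(p)), capped at 1000."""
    if pvalue is None or not np.isfinite(pvalue):
        return 0
    if pvalue <= 0:
        return 1000
    return min(1000, int(round(-10.0 * math.log10(pvalue))))


def write_bed6(rows, path, chrom: str = "genome") -> None:
    """Write (start, end, name, pvalue, strand) rows as BED6."""
    with open(path, "w") as fh:
        for start, end, name, pvalue, strand in rows:
            fh.write(
                f"{chrom}\t{start}\t{end}\t{name}\t{bed_score(pvalue)}\t{strand}\n"
            )


# ---------------------------------------------------------------------------
# Fold-change tables
# ---------------------------------------------------------------------------

def read_fold_change_table(path) -> pd.DataFrame:
    """Read a TSV fold-change table with columns feature_id, log2fc, pvalue.

    Optional columns (padj, contrast_id) are preserved.  "NA" p-values are
    kept as missing; records with missing p are excluded from significance
    calls downstream, never dropped here.
    """
    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str},
                     na_values=["NA", "NaN", ""])
    required = {"feature_id", "log2fc", "pvalue"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    if df["feature_id"].duplicated().any():
        dup = df.loc[df["feature_id"].duplicated(), "feature_id"].iloc[0]
        raise ValueError(f"{path}: duplicated feature_id {dup!r}")
    for col in ("log2fc", "pvalue"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(
                f"{path}: non-numeric {col} in row for feature "
                f"{df.loc[row, 'feature_id']!r}"
            )
        df[col] = coerced
    return df


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
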