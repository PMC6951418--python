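"""Genomic coordinate model: intervals, transcripts, and promoter/body regions.

All coordinates are 0-based half-open (BED convention). GTF input, which is
1-based inclusive, is converted on read. The transcription start site (TSS) of
a minus-strand transcript is its maximal genomic coordinate.

The two regions every downstream feature is computed on are

* the **TSS interval**: a symmetric window of ``flank`` bp (default 500) on
  each side of the TSS, clipped at chromosome boundaries, and
* the **gene body**: from ``flank`` bp downstream of the TSS (in transcript
  orientation) to the transcription termination site (TTS).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

log = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class Transcript:
    """A transcript record with optional exon structure and expression level.

    Exons are carried for completeness but all region-level statistics are
    computed on the transcript interval; multi-exon structure does not enter
    the feature definitions.
    """

    id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    fpkm: float | None = None

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"transcript {self.id}: strand must be + or -")
        if not self.exons:
            self.exons = [self.interval]
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.interval.chrom:
                raise ValueError(f"transcript {self.id}: exon on wrong chromosome")
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"transcript {self.id}: exon outside interval")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"transcript {self.id}: exons unsorted or overlapping")
            prev_end = ex.end

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        """TSS coordinate: interval.start on +, interval.end on -."""
        return self.interval.start if self.strand == "+" else self.interval.end

    @property
    def tts(self) -> int:
        return self.interval.end if self.strand == "+" else self.interval.start

    @property
    def length(self) -> int:
        return self.interval.width


def make_tss_interval(
    t: Transcript, flank: int = 500, chrom_len: int | None = None
) -> GenomicInterval:
    """Symmetric ``flank``-bp window around the TSS, clipped to the chromosome.

    Windows truncated at a chromosome boundary are kept (clipped) rather than
    discarded, so the transcript universe is stable under region derivation.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    if chrom_len is not None and chrom_len <= 0:
        raise ValueError("chrom_len must be positive")
    tss = t.tss
    start = max(0, tss - flank)
    end = tss + flank
    if chrom_len is not None:
        end = min(end, chrom_len)
    if start >= end:
        raise ValueError(f"transcript {t.id}: TSS window empty after clipping")
    return GenomicInterval(t.chrom, start, end, t.strand)


def make_body_region(t: Transcript, flank: int = 500) -> GenomicInterval:
    """Gene body: from ``flank`` bp downstream of the TSS to the TTS.

    Raises ``ValueError`` for transcripts of genomic length <= ``flank``,
    whose body region would be empty.
    """
    if t.length <= flank:
        raise ValueError(
            f"transcript {t.id}: length {t.length} <= flank {flank}, empty body"
        )
    if t.strand == "+":
        return GenomicInterval(t.chrom, t.interval.start + flank, t.interval.end, "+")
    return GenomicInterval(t.chrom, t.interval.start, t.interval.end - flank, "-")


def expressed_filter(
    transcripts: Sequence[Transcript], min_fpkm: float = 0.5
) -> list[Transcript]:
    """Keep transcripts with FPKM >= ``min_fpkm``, preserving order."""
    for t in transcripts:
        if t.fpkm is None:
            raise ValueError(f"transcript {t.id} has no FPKM value")
    return [t for t in transcripts if t.fpkm >= min_fpkm]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_gtf(path: str | Path) -> list[Transcript]:
    """Read transcripts (with exons) from a GTF file via gffutils.

    GTF 1-based inclusive coordinates are converted to 0-based half-open.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    transcripts = []
    for tf in db.features_of_type("transcript"):
        tid = tf.attributes["transcript_id"][0]
        iv = GenomicInterval(tf.seqid, tf.start - 1, tf.end, tf.strand)
        exons = [
            GenomicInterval(e.seqid, e.start - 1, e.end, e.strand)
            for e in db.children(tf, featuretype="exon", order_by="start")
        ]
        transcripts.append(Transcript(tid, iv, exons or [iv]))
    return transcripts


def read_bed12(path: str | Path) -> list[Transcript]:
    """Read transcripts from a BED12 file (block fields give exons)."""
    transcripts = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                log.warning("%s:%d: skipping short BED12 line", path, lineno)
                continue
            chrom, start, end, name, _, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            iv = GenomicInterval(chrom, start, end, strand)
            exons = [
                GenomicInterval(chrom, start + s, start + s + sz, strand)
                for s, sz in zip(starts, sizes)
            ]
            transcripts.append(Transcript(name, iv, exons))
    return transcripts


def read_bed6(path: str | Path) -> list[GenomicInterval]:
    """Read plain intervals from a BED file (3-6 columns)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                log.warning("%s:%d: skipping malformed BED line", path, lineno)
                continue
            strand = f[5] if len(f) >= 6 and f[5] in ("+", "-") else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return out


def write_bed6(
    intervals: Iterable[GenomicInterval],
    path: str | Path,
    names: Iterable[str] | None = None,
) -> None:
    names = list(names) if names is not None else None
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names else f"iv{i}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def write_bed12(transcripts: Iterable[Transcript], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            sizes = ",".join(str(e.width) for e in t.exons)
            starts = ",".join(str(e.start - t.interval.start) for e in t.exons)
            fh.write(
                f"{t.chrom}\t{t.interval.start}\t{t.interval.end}\t{t.id}\t0\t"
                f"{t.strand}\t{t.interval.start}\t{t.interval.end}\t0\t"
                f"{len(t.exons)}\t{sizes}\t{starts}\n"
            )


def read_expression_tsv(path: str | Path) -> dict[str, float]:
    """Read an (id, fpkm) TSV into a dict; a header row is optional."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (id, fpkm)")
    first = df.iloc[0, 1]
    try:
        float(first)
    except ValueError:
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1].astype(float)))


def attach_expression(
    transcripts: Sequence[Transcript], fpkm: dict[str, float]
) -> list[Transcript]:
    """Return transcripts with FPKM values attached from a lookup table."""
    out = []
    for t in transcripts:
        if t.id not in fpkm:
            raise KeyError(f"no expression value for transcript {t.id}")
        out.append(Transcript(t.id, t.interval, list(t.exons), fpkm[t.id]))
    return out
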