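"""Readers and writers for the on-disk formats the pipeline touches.

All internal coordinates are 0-based half-open (BED convention). Conversion
to or from 1-based display coordinates happens only at serialization
boundaries; nothing in the library stores 1-based positions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

__all__ = [
    "FormatError",
    "SequenceRecord",
    "GenomicInterval",
    "GeneModel",
    "ReadPairRecord",
    "read_fasta",
    "write_fasta",
    "read_fastq_pairs",
    "write_fastq_pairs",
    "read_bed",
    "write_bed",
    "read_gene_models",
    "write_gene_models",
    "read_genus_map",
    "write_genus_map",
    "EVENT_COLUMNS",
    "write_events_tsv",
    "read_events_tsv",
    "write_matrix_tsv",
    "read_matrix_tsv",
]


class FormatError(ValueError):
    """A malformed input file or an invariant violation on read."""


@dataclass(frozen=True)
class SequenceRecord:
    """One named sequence; the sequence is stored uppercased."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.sequence:
            raise FormatError(f"sequence record {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval on a named sequence; strand '.' means unstranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise FormatError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class GeneModel:
    """A gene with transcript span, CDS span and exon structure.

    A gene without a CDS (``cds_start == cds_end``) is treated as
    non-coding. Exons are sorted, non-overlapping and contained in the
    transcript span; the CDS, when present, is contained in the span too.
    """

    gene_name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_name}: invalid strand")
        if not (0 <= self.tx_start < self.tx_end):
            raise FormatError(f"gene {self.gene_name}: invalid tx span")
        if self.cds_start != self.cds_end and not (
            self.tx_start <= self.cds_start < self.cds_end <= self.tx_end
        ):
            raise FormatError(f"gene {self.gene_name}: CDS outside tx span")
        if len(self.exon_starts) != len(self.exon_ends) or not self.exon_starts:
            raise FormatError(f"gene {self.gene_name}: bad exon lists")
        prev_end = self.tx_start - 1
        for s, e in zip(self.exon_starts, self.exon_ends):
            if not (self.tx_start <= s < e <= self.tx_end):
                raise FormatError(f"gene {self.gene_name}: exon outside tx span")
            if s <= prev_end:
                raise FormatError(
                    f"gene {self.gene_name}: exons unsorted or overlapping"
                )
            prev_end = e

    @property
    def is_coding(self) -> bool:
        return self.cds_start != self.cds_end

    @property
    def n_exons(self) -> int:
        return len(self.exon_starts)

    def exons(self) -> Iterator[tuple[int, int]]:
        return zip(self.exon_starts, self.exon_ends)


@dataclass
class ReadPairRecord:
    """One sequenced fragment: two mates plus optional simulation truth."""

    pair_id: str
    seq1: str
    seq2: str
    qual1: str = ""
    qual2: str = ""
    truth_class: str | None = None

    def __post_init__(self) -> None:
        if not self.qual1:
            self.qual1 = "I" * len(self.seq1)
        if not self.qual2:
            self.qual2 = "I" * len(self.seq2)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file; sequences are uppercased, order preserved."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    name: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if name is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise FormatError(f"FASTA record {name!r} has no sequence")
        if name in seen:
            raise FormatError(f"duplicate FASTA id {name!r}")
        seen.add(name)
        records.append(SequenceRecord(name, seq))

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0] if line[1:].strip() else ""
                if not name:
                    raise FormatError("FASTA header with empty id")
                chunks = []
            else:
                if name is None:
                    raise FormatError("FASTA sequence before first header")
                chunks.append(line.strip())
        flush()
    if not records:
        raise FormatError(f"empty FASTA file: {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ

def _strip_mate_suffix(read_id: str, mate: int) -> str:
    for suffix in (f"/{mate}", f".{mate}"):
        if read_id.endswith(suffix):
            return read_id[: -len(suffix)]
    return read_id


def _iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            header = header.rstrip("\n")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+"):
                raise FormatError(f"malformed FASTQ record near {header!r}")
            if len(seq) != len(qual):
                raise FormatError(
                    f"FASTQ record {header!r}: sequence/quality length mismatch"
                )
            yield header[1:].split()[0], seq.upper(), qual


def read_fastq_pairs(path_r1: str | Path,
                     path_r2: str | Path) -> Iterator[ReadPairRecord]:
    """Stream mate pairs from two synchronized FASTQ files.

    Mate suffixes ``/1`` and ``/2`` (or bare duplicated ids) are accepted;
    ids must match after suffix stripping, record for record.
    """
    it1, it2 = _iter_fastq(path_r1), _iter_fastq(path_r2)
    sentinel = object()
    while True:
        rec1 = next(it1, sentinel)
        rec2 = next(it2, sentinel)
        if rec1 is sentinel and rec2 is sentinel:
            return
        if rec1 is sentinel or rec2 is sentinel:
            raise FormatError("R1/R2 record counts differ")
        id1 = _strip_mate_suffix(rec1[0], 1)
        id2 = _strip_mate_suffix(rec2[0], 2)
        if id1 != id2:
            raise FormatError(f"mate id mismatch: {rec1[0]!r} vs {rec2[0]!r}")
        yield ReadPairRecord(id1, rec1[1], rec2[1], rec1[2], rec2[2])


def write_fastq_pairs(pairs: Iterable[ReadPairRecord],
                      path_r1: str | Path, path_r2: str | Path) -> None:
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.pair_id}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.pair_id}/2\n{p.seq2}\n+\n{p.qual2}\n")


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ intervals (0-based half-open, as stored internally)."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            intervals.append(GenomicInterval(chrom, start, end, strand))
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# Gene model table (refGene-like, all coordinates 0-based half-open)

_GENE_COLUMNS = [
    "gene_name", "chrom", "strand", "tx_start", "tx_end",
    "cds_start", "cds_end", "exon_starts", "exon_ends",
]


def read_gene_models(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_GENE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"gene model table missing columns: {sorted(missing)}")
    models = []
    for row in df.itertuples(index=False):
        models.append(
            GeneModel(
                gene_name=row.gene_name,
                chrom=row.chrom,
                strand=row.strand,
                tx_start=int(row.tx_start),
                tx_end=int(row.tx_end),
                cds_start=int(row.cds_start),
                cds_end=int(row.cds_end),
                exon_starts=tuple(
                    int(x) for x in str(row.exon_starts).rstrip(",").split(",")
                ),
                exon_ends=tuple(
                    int(x) for x in str(row.exon_ends).rstrip(",").split(",")
                ),
            )
        )
    return models


def write_gene_models(models: Iterable[GeneModel], path: str | Path) -> None:
    rows = []
    for g in models:
        rows.append(
            {
                "gene_name": g.gene_name,
                "chrom": g.chrom,
                "strand": g.strand,
                "tx_start": g.tx_start,
                "tx_end": g.tx_end,
                "cds_start": g.cds_start,
                "cds_end": g.cds_end,
                "exon_starts": ",".join(str(x) for x in g.exon_starts),
                "exon_ends": ",".join(str(x) for x in g.exon_ends),
            }
        )
    pd.DataFrame(rows, columns=_GENE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genus metadata (accession -> genus)

def read_genus_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"accession", "genus"} <= set(df.columns):
        raise FormatError("genus map needs 'accession' and 'genus' columns")
    if df["accession"].duplicated().any():
        raise FormatError("duplicate accession in genus map")
    return dict(zip(df["accession"], df["genus"]))


def write_genus_map(genus_map: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        sorted(genus_map.items()), columns=["accession", "genus"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Event table and generic matrices

EVENT_COLUMNS = [
    "sample_id", "pair_id", "host_chrom", "host_start", "host_end",
    "host_strand", "bact_accession", "bact_genus", "bact_start", "bact_end",
    "gene_name", "region_class",
]

_EVENT_INT_COLUMNS = ["host_start", "host_end", "bact_start", "bact_end"]


def write_events_tsv(events: pd.DataFrame, path: str | Path) -> None:
    """Write an event table; columns are reordered to the canonical layout."""
    missing = set(EVENT_COLUMNS) - set(events.columns)
    if missing:
        raise FormatError(f"event table missing columns: {sorted(missing)}")
    events[EVENT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"event table missing columns: {sorted(missing)}")
    for col in _EVENT_INT_COLUMNS:
        df[col] = df[col].astype(int)
    return df[EVENT_COLUMNS]


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index=True, index_label="sample_id")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")
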