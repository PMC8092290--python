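"""Readers and writers for the standard formats the pipeline touches.

Internal coordinate convention: 0-based half-open intervals on the forward
genome strand, strands ``+``/``-``.  All conversion from 1-based inclusive
source coordinates (GFF3, GenBank feature tables) happens at the I/O
boundary, never downstream.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FormatError",
    "ParameterError",
    "GenomeRecord",
    "OrfFeature",
    "ReadRecord",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_features",
    "write_gff3",
    "to_internal",
    "to_external",
]


class FormatError(ValueError):
    """A file did not conform to its declared format."""


class ParameterError(ValueError):
    """A configuration or argument value is out of its valid domain."""


@dataclass
class OrfFeature:
    """A CDS/ORF on a genome; 0-based half-open, strand-aware."""

    id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"feature {self.id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"feature {self.id}: unknown strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, start: int, end: int) -> bool:
        """True when [start, end) lies fully inside this feature."""
        return self.start <= start and end <= self.end


@dataclass
class GenomeRecord:
    """A reference sequence with its ORF annotation.

    ``topology`` distinguishes linear genomes (physical ends defined, e.g. a
    dsDNA phage chromosome) from circular bacterial chromosomes; flank
    extraction wraps on circular genomes and truncates on linear ones.
    """

    id: str
    sequence: str
    topology: str = "linear"
    features: list[OrfFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise FormatError(f"genome {self.id}: empty sequence")
        if self.topology not in ("linear", "circular"):
            raise ParameterError(f"genome {self.id}: topology {self.topology!r}")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise FormatError(f"genome {self.id}: non-ACGTN characters {sorted(bad)}")
        for f in self.features:
            if f.end > len(self.sequence):
                raise FormatError(
                    f"genome {self.id}: feature {f.id} extends past sequence end"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadRecord:
    """One sequencing read with Sanger-offset (Phred+33) qualities."""

    id: str
    sequence: str
    qualities: list[int]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise FormatError(
                f"read {self.id}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )
        if self.qualities and not (0 <= min(self.qualities) <= max(self.qualities) <= 93):
            raise FormatError(f"read {self.id}: quality out of Phred range [0, 93]")

    def __len__(self) -> int:
        return len(self.sequence)


# --- coordinate conversion ------------------------------------------------

def to_internal(start_1based: int, end_inclusive: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start_1based - 1, end_inclusive


def to_external(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive (inverse of :func:`to_internal`)."""
    return start + 1, end


# --- FASTA ----------------------------------------------------------------

def read_fasta(path: str | Path, topology: str = "linear") -> list[GenomeRecord]:
    """Read a FASTA file into :class:`GenomeRecord` objects.

    Sequences are upper-cased and U is mapped to T.  Duplicate record IDs and
    empty sequences are format errors.
    """
    path = Path(path)
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(GenomeRecord(id=rec.id, sequence=seq, topology=topology))
    if not records:
        # distinguish an empty file from a parse failure
        text = path.read_text()
        if text.strip():
            raise FormatError(f"{path}: no FASTA records parsed (malformed header?)")
    return records


def write_fasta(records, path: str | Path, width: int = 70) -> None:
    """Write GenomeRecords (or any objects with .id/.sequence) as FASTA."""
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


# --- FASTQ ----------------------------------------------------------------

def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream :class:`ReadRecord` objects from a Phred+33 FASTQ file.

    Records are yielded lazily; the whole file is never loaded.  A
    sequence/quality length mismatch raises a :class:`FormatError` naming the
    offending record.
    """
    path = Path(path)
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            yield ReadRecord(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                qualities=list(rec.letter_annotations["phred_quality"]),
            )
    except ValueError as exc:  # Biopython reports the record title in the message
        raise FormatError(f"{path}: {exc}") from exc


def write_fastq(reads, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


# --- features (GFF3 / flat GenBank-style table) ---------------------------

def read_features(path: str | Path, dialect: str = "gff3") -> list[OrfFeature]:
    """Read CDS features, converting 1-based inclusive coordinates to internal.

    ``gff3``: standard 9-column GFF3; only rows of type ``CDS`` are retained.
    ``genbank_table``: flat tab-separated ``id<TAB>start<TAB>end<TAB>strand``
    (1-based inclusive), the minimal slice of a GenBank feature table.
    """
    path = Path(path)
    if dialect not in ("gff3", "genbank_table"):
        raise ParameterError(f"unknown feature dialect {dialect!r}")
    features: list[OrfFeature] = []
    counter = itertools.count(1)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            try:
                if dialect == "gff3":
                    if len(cols) < 8:
                        raise FormatError("fewer than 8 columns")
                    if cols[2] != "CDS":
                        continue
                    fid = _gff3_id(cols[8] if len(cols) > 8 else "", counter)
                    start1, end1, strand = int(cols[3]), int(cols[4]), cols[6]
                else:
                    if len(cols) != 4:
                        raise FormatError("expected 4 columns (id, start, end, strand)")
                    fid, start1, end1, strand = cols[0], int(cols[1]), int(cols[2]), cols[3]
                if end1 < start1:
                    raise FormatError(f"end {end1} < start {start1}")
                start, end = to_internal(start1, end1)
                features.append(OrfFeature(id=fid, start=start, end=end, strand=strand))
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return features


def _gff3_id(attributes: str, counter) -> str:
    for part in attributes.split(";"):
        part = part.strip()
        if part.startswith("ID="):
            return part[3:]
    return f"cds_{next(counter)}"


def write_gff3(genome: GenomeRecord, path: str | Path) -> None:
    """Write a genome's CDS features as GFF3 (1-based inclusive on output)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {len(genome)}\n")
        for f in genome.features:
            start1, end1 = to_external(f.start, f.end)
            fh.write(
                f"{genome.id}\t.\tCDS\t{start1}\t{end1}\t.\t{f.strand}\t0\tID={f.id}\n"
            )
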