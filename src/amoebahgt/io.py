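"""FASTA and GFF3 input/output for scaffolds and gene models.

FASTA goes through Bio.SeqIO.  GFF3 is written/read directly: the subset used
here is CDS rows with ``ID`` attributes, and the write→read→write contract must
be byte-stable, which rules out database-backed ingest layers.

Coordinates are 1-based inclusive throughout, as in the GFF3 standard; the
coordinate span of a gene includes its stop codon.
"""

from __future__ import annotations

import urllib.parse
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ArgumentError, ParseError

GFF3_PRAGMA = "##gff-version 3"


@dataclass(frozen=True)
class Scaffold:
    """A genomic scaffold: DNA over {A,C,G,T,N}."""

    scaffold_id: str
    sequence: str
    genome_id: str = ""

    def __post_init__(self):
        if not self.sequence:
            raise ArgumentError(f"scaffold {self.scaffold_id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class OrfRecord:
    """A predicted protein-coding gene on a scaffold.

    ``start``/``end`` are 1-based inclusive nucleotide coordinates on the
    forward strand and span the stop codon, so
    ``len(protein) == (end - start + 1) // 3 - 1``.
    """

    gene_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str
    frame: int
    protein: str = ""

    def __post_init__(self):
        if self.end < self.start:
            raise ArgumentError(
                f"ORF {self.gene_id!r}: end {self.end} < start {self.start}"
            )
        if (self.end - self.start + 1) % 3 != 0:
            raise ArgumentError(f"ORF {self.gene_id!r}: span not divisible by 3")
        if self.strand not in ("+", "-"):
            raise ArgumentError(f"ORF {self.gene_id!r}: bad strand {self.strand!r}")

    @property
    def length_aa(self) -> int:
        return (self.end - self.start + 1) // 3 - 1


def read_fasta(path: str | Path, genome_id: str = "") -> list[Scaffold]:
    """Read a FASTA file into scaffolds.  An empty file yields an empty list."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(Scaffold(rec.id, str(rec.seq).upper(), genome_id))
    return records


def write_fasta(records: Iterable[Scaffold] | Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write scaffolds or (id, sequence) pairs as FASTA (60-column wrap)."""
    seqrecords = []
    for rec in records:
        if isinstance(rec, Scaffold):
            seqrecords.append(SeqRecord(Seq(rec.sequence), id=rec.scaffold_id, description=""))
        else:
            name, seq = rec
            seqrecords.append(SeqRecord(Seq(seq), id=name, description=""))
    with open(path, "w") as fh:
        SeqIO.write(seqrecords, fh, "fasta")


def read_protein_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a protein FASTA as (id, sequence) pairs."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_gff3(orfs: Iterable[OrfRecord], path: str | Path, source: str = "amoebahgt") -> None:
    with open(path, "w") as fh:
        fh.write(GFF3_PRAGMA + "\n")
        for orf in orfs:
            attrs = f"ID={urllib.parse.quote(orf.gene_id)}"
            fh.write(
                "\t".join(
                    [
                        orf.scaffold_id,
                        source,
                        "CDS",
                        str(orf.start),
                        str(orf.end),
                        ".",
                        orf.strand,
                        "0",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gff3(
    path: str | Path,
    scaffolds: dict[str, Scaffold] | None = None,
) -> list[OrfRecord]:
    """Read CDS rows of a GFF3 file into OrfRecords.

    When ``scaffolds`` is given, protein translations are reconstructed from
    the scaffold sequences; otherwise ``protein`` is left empty.

    Raises :class:`ParseError` (with the line number) on malformed rows,
    including ``end < start``.
    """
    from .seqcore import extract_protein  # local import: avoid cycle

    orfs: list[OrfRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"expected 9 tab-separated fields, got {len(fields)}", lineno)
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            if ftype != "CDS":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"non-integer coordinates {start_s!r}/{end_s!r}", lineno) from None
            if end < start:
                raise ParseError(f"end {end} < start {start}", lineno)
            gene_id = ""
            for part in attrs.split(";"):
                if part.startswith("ID="):
                    gene_id = urllib.parse.unquote(part[3:])
            if not gene_id:
                raise ParseError("CDS row without ID attribute", lineno)
            protein = ""
            if scaffolds is not None:
                if seqid not in scaffolds:
                    raise ParseError(f"unknown scaffold {seqid!r}", lineno)
                protein = extract_protein(scaffolds[seqid].sequence, start, end, strand)
            try:
                orfs.append(
                    OrfRecord(gene_id, seqid, start, end, strand, (start - 1) % 3, protein)
                )
            except ArgumentError as exc:
                raise ParseError(str(exc), lineno) from None
    return orfs
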