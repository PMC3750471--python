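"""Reading, validating and writing DNA sequences; genomic-region arithmetic.

Coordinate convention
---------------------
All genomic coordinates in this package are **1-based and inclusive on both
ends**, the convention used by NCBI sequence viewers and GenBank feature
tables.  The length of a region is therefore ``end - start + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

from .errors import (
    CoordinateError,
    EmptyInputError,
    FastaFormatError,
    SequenceValidationError,
)

#: Canonical alphabet accepted after validation.  'N' (unknown base) is
#: tolerated at parse time; its numeric treatment is decided by
#: :mod:`phasewarp.signal_transform`.
ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class DNASequence:
    """A validated DNA sequence: identifier plus uppercase A/C/G/T/N string."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        validate_sequence(self.seq, label=self.id)

    @property
    def length(self) -> int:
        return len(self.seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GenomicRegion:
    """A 1-based, both-ends-inclusive region on a named sequence."""

    accession: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise CoordinateError(
                f"{self.accession}: start must be >= 1 (got {self.start})"
            )
        if self.end < self.start:
            raise CoordinateError(
                f"{self.accession}: end ({self.end}) < start ({self.start})"
            )


def validate_sequence(seq: str, label: str = "<sequence>") -> str:
    """Check that ``seq`` uses only A/C/G/T/N; report the first offender.

    Positions in the error message are 1-based.
    """
    for pos, char in enumerate(seq, start=1):
        if char not in ALPHABET:
            raise SequenceValidationError(
                f"{label}: invalid character {char!r} at position {pos} "
                f"(allowed: A, C, G, T, N)"
            )
    return seq


def read_fasta(path: Union[str, Path]) -> List[DNASequence]:
    """Read a (multi-)FASTA file into validated :class:`DNASequence` records.

    Record ids are the header text up to the first whitespace; sequences are
    uppercased.  Raises :class:`FastaFormatError` for non-FASTA content,
    :class:`EmptyInputError` for a file with no records, and
    :class:`SequenceValidationError` for characters outside A/C/G/T/N.
    """
    path = Path(path)
    text = path.read_text()
    stripped = text.lstrip()
    if not stripped:
        raise EmptyInputError(f"{path}: FASTA file contains no records")
    if not stripped.startswith(">"):
        raise FastaFormatError(
            f"{path}: sequence data appears before the first '>' header"
        )
    records = []
    with path.open() as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            records.append(DNASequence(id=rec.id, seq=str(rec.seq).upper()))
    if not records:
        raise EmptyInputError(f"{path}: FASTA file contains no records")
    return records


def write_fasta(
    records: Iterable[DNASequence], path: Union[str, Path], width: int = 70
) -> None:
    """Write records as FASTA wrapped at ``width`` columns.

    Round-trips with :func:`read_fasta`.  An empty record list is an error.
    """
    records = list(records)
    if not records:
        raise EmptyInputError("write_fasta: no records to write")
    if width < 1:
        raise ValueError(f"width must be >= 1 (got {width})")
    seq_records = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as handle:
        writer = FastaWriter(handle, wrap=width)
        writer.write_file(seq_records)


def region_length(region: GenomicRegion) -> int:
    """Length in bp of a 1-based inclusive region: ``end - start + 1``."""
    return region.end - region.start + 1


@dataclass(frozen=True)
class ReferenceGene:
    """One entry of the ACTA1 reference panel: organism plus its gene region."""

    organism: str
    chromosome: str
    region: GenomicRegion


#: The ten ACTA1 (skeletal-muscle alpha-actin) gene regions used as the
#: method's demonstration panel: nine mammals and one bird, complete genes
#: including introns, ~2900 bp each.  Coordinates are the NCBI chromosome
#: positions of each gene.
ACTA1_PANEL: tuple = (
    ReferenceGene("Homo sapiens", "1", GenomicRegion("NC_000001.10", 229566993, 229569844)),
    ReferenceGene("Pongo abelii", "1", GenomicRegion("NC_012591.1", 20230379, 20233215)),
    ReferenceGene("Macaca mulatta", "1", GenomicRegion("NC_007858.1", 227524284, 227527141)),
    ReferenceGene("Callithrix jacchus", "19", GenomicRegion("NC_013914.1", 15737624, 15740450)),
    ReferenceGene("Mus musculus", "8", GenomicRegion("NC_000074.5", 126415668, 126418637)),
    ReferenceGene("Rattus norvegicus", "19", GenomicRegion("NC_005118.2", 54081497, 54084509)),
    ReferenceGene("Sus scrofa", "14", GenomicRegion("NC_010456.4", 65236451, 65239197)),
    ReferenceGene("Bos taurus", "28", GenomicRegion("NC_007329.5", 427530, 430286)),
    ReferenceGene("Equus caballus", "1", GenomicRegion("NC_009144.2", 68408850, 68411788)),
    ReferenceGene("Gallus gallus", "3", GenomicRegion("NC_006090.3", 39337938, 39340802)),
)
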