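"""Genome and locus/CDS input handling.

The organism genome is a (possibly multi-record) FASTA used only for exact
off-target counting; records are kept separate so matches never span record
boundaries.  'N' bases are accepted in the genome — they simply never match a
guide.  A ``.txt`` extension is accepted for renamed FASTA downloads.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

from Bio import SeqIO

from .errors import GenomeLoadError, MissingGenomeError

logger = logging.getLogger(__name__)

#: legacy genome filename looked up in the working directory when no
#: explicit genome path is given
MAGIC_GENOME_FILENAME = "INSERT_ORGANISM_GENOME_HERE.txt"


@dataclass(frozen=True)
class Genome:
    """A set of named, uppercased genome sequences."""

    records: tuple[tuple[str, str], ...]

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def total_length(self) -> int:
        return sum(len(seq) for _id, seq in self.records)

    @classmethod
    def from_records(cls, records) -> "Genome":
        return cls(tuple((rid, seq.upper()) for rid, seq in records))


def load_genome(path: str | os.PathLike) -> Genome:
    """Load a genome FASTA (``.fa``/``.fasta``/renamed ``.txt``).

    Sequences are uppercased on load.  A missing file raises
    MissingGenomeError; an unreadable or record-free file raises
    GenomeLoadError.
    """
    if not os.path.exists(path):
        raise MissingGenomeError(
            f"genome file {path!s} not found; download the organism genome in "
            "FASTA format and point --genome at it"
        )
    try:
        records = [
            (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
        ]
    except Exception as exc:  # malformed FASTA
        raise GenomeLoadError(f"could not parse {path!s} as FASTA: {exc}") from exc
    if not records:
        raise GenomeLoadError(f"no FASTA records found in {path!s}")
    genome = Genome(tuple(records))
    logger.info(
        "loaded genome: %d record(s), %d nt total", len(genome), genome.total_length
    )
    return genome


def read_sequence_input(value: str, *, preserve_case: bool = True) -> str:
    """Resolve a locus or CDS argument that is either a raw DNA string or a
    path to a single-record FASTA file.

    FASTA parsing preserves case, which carries the intron/exon encoding of a
    locus.
    """
    if os.path.exists(value) and not set(value) <= set("ACGTacgtNn"):
        records = list(SeqIO.parse(value, "fasta"))
        if len(records) != 1:
            raise GenomeLoadError(
                f"expected a single-record FASTA at {value!s}, found {len(records)}"
            )
        seq = str(records[0].seq)
        return seq if preserve_case else seq.upper()
    return value
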