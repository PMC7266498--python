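"""Case-encoded locus parsing, CDS derivation and the codon-position matrix.

A gene is supplied as its genomic locus with exons in UPPERCASE and introns /
UTRs in lowercase, 5'->3'.  Optional upstream and downstream flanks extend the
searchable sequence near the protein termini; they are always non-coding
regardless of their input case.  All genomic coordinates are 0-based
internally; residue positions exposed to users are 1-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .errors import (
    CdsMismatchError,
    FrameError,
    InvalidSequenceError,
    NoExonsError,
)

logger = logging.getLogger(__name__)

_DNA_CHARS = set("ACGTacgt")
_REVCOMP_TABLE = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    """Case-preserving Watson-Crick reverse complement; N pairs with N."""
    for i, ch in enumerate(seq):
        if ch not in "ACGTacgtNn":
            raise InvalidSequenceError(ch, i)
    return seq.translate(_REVCOMP_TABLE)[::-1]


@dataclass(frozen=True)
class AnnotatedLocus:
    """A genomic locus with flanks and the coordinates of its exonic bases.

    ``sequence`` is the full concatenation upstream_flank + locus +
    downstream_flank, preserving the locus case encoding (flanks are
    lowercase-normalised).  ``exon_positions`` indexes the exonic (uppercase)
    bases of the locus within that full sequence, in strictly increasing
    order.
    """

    sequence: str
    upstream_flank: str = ""
    downstream_flank: str = ""
    exon_positions: tuple[int, ...] = field(default=())

    @property
    def cds(self) -> str:
        return derive_cds(self)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CodonRecord:
    """One protein residue with its codon and genomic base coordinates."""

    index: int  # 1-based residue position
    amino_acid: str  # single-letter code, '*' for a stop
    codon: str  # 3-nt DNA, uppercase
    base_positions: tuple[int, int, int]  # 0-based, strictly increasing


@dataclass(frozen=True)
class CodonMatrix:
    """Per-residue mapping of protein position -> codon -> genomic coordinates."""

    residues: tuple[CodonRecord, ...]

    @property
    def protein(self) -> str:
        return "".join(r.amino_acid for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, residue_position: int) -> CodonRecord:
        """Look up a residue by its 1-based position."""
        return self.residues[residue_position - 1]


def _check_dna(seq: str, context: str) -> None:
    for i, ch in enumerate(seq):
        if ch not in _DNA_CHARS:
            raise InvalidSequenceError(ch, i, context)


def parse_locus(raw_locus: str, upstream: str = "", downstream: str = "") -> AnnotatedLocus:
    """Parse a case-encoded locus and optional flanks into an AnnotatedLocus.

    Uppercase characters of ``raw_locus`` are exonic; flanks are forced
    non-exonic whatever their case.  Raises InvalidSequenceError for non-DNA
    characters and NoExonsError when the locus has no uppercase base.
    """
    if not raw_locus:
        raise NoExonsError("empty locus")
    _check_dna(raw_locus, "locus")
    _check_dna(upstream, "upstream flank")
    _check_dna(downstream, "downstream flank")

    up = upstream.lower()
    down = downstream.lower()
    offset = len(up)
    exon_positions = tuple(
        offset + i for i, ch in enumerate(raw_locus) if ch.isupper()
    )
    if not exon_positions:
        raise NoExonsError("locus contains no uppercase (exonic) bases")
    return AnnotatedLocus(
        sequence=up + raw_locus + down,
        upstream_flank=up,
        downstream_flank=down,
        exon_positions=exon_positions,
    )


def derive_cds(locus: AnnotatedLocus) -> str:
    """Concatenate the exonic bases 5'->3' into the coding sequence."""
    return "".join(locus.sequence[i] for i in locus.exon_positions).upper()


def validate_cds(locus: AnnotatedLocus, user_cds: str) -> bool:
    """Check the exon-derived CDS against the user-supplied one.

    Comparison is exact string identity after uppercasing.  On mismatch a
    CdsMismatchError carrying the first differing index is raised; guides must
    not be generated from an inconsistent locus/CDS pair.
    """
    derived = derive_cds(locus)
    supplied = user_cds.upper()
    if derived == supplied:
        return True
    for i, (a, b) in enumerate(zip(derived, supplied)):
        if a != b:
            raise CdsMismatchError(i)
    raise CdsMismatchError(min(len(derived), len(supplied)))


def translate(cds: str) -> str:
    """Translate a CDS with the standard genetic code; stops render as '*'."""
    if len(cds) % 3 != 0:
        raise FrameError(
            f"CDS length {len(cds)} is not divisible by 3; refusing to "
            "truncate, as that would corrupt residue indexing"
        )
    cds = cds.upper()
    for i, ch in enumerate(cds):
        if ch not in "ACGT":
            raise InvalidSequenceError(ch, i, "CDS")
    return str(Seq(cds).translate())


def build_codon_matrix(locus: AnnotatedLocus, cds: str | None = None) -> CodonMatrix:
    """Build the residue -> codon -> genomic-coordinate matrix.

    Residue i (1-based) maps to codon cds[3i-3:3i] and to the corresponding
    triple of exon positions.  A terminal stop codon is kept as residue '*'.
    """
    if cds is None:
        cds = derive_cds(locus)
    else:
        validate_cds(locus, cds)
        cds = cds.upper()
    if len(cds) % 3 != 0:
        raise FrameError(
            f"CDS length {len(cds)} is not divisible by 3"
        )
    protein = translate(cds)
    records = []
    for i, aa in enumerate(protein):
        pos = locus.exon_positions[3 * i : 3 * i + 3]
        records.append(
            CodonRecord(
                index=i + 1,
                amino_acid=aa,
                codon=cds[3 * i : 3 * i + 3],
                base_positions=(pos[0], pos[1], pos[2]),
            )
        )
    return CodonMatrix(residues=tuple(records))
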