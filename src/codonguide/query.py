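"""Position-specific and type-specific residue queries.

The signed cut-site-to-codon distance follows four strand/direction rules.
With the cut between forward-locus indices ``c`` (= ``cut5_index``) and
``c + 1``, and the target codon's first/last genomic bases ``L`` / ``R``:

* forward strand, guide upstream of the codon (positive):  ``L - (c + 1)``
  — right-hand base of the cut to the left-hand base of the codon;
* forward strand, guide downstream (negative): magnitude ``c - R``
  — left-hand base of the cut to the right-hand base of the codon;
* reverse strand, upstream (positive): ``L - c``
  — left-hand base of the cut to the left-hand base of the codon;
* reverse strand, downstream (negative): magnitude ``(c + 1) - R``
  — right-hand base of the cut to the right-hand base of the codon.

A cut falling inside the codon's genomic span yields distance 0, and
zero-distance guides are classified as upstream/5' for list assignment.
Distances are measured along genomic DNA, so a codon split by an intron keeps
its genomic endpoints and an intervening intron inflates distances — which is
what homology-directed repair efficiency actually depends on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .errors import PositionError
from .guides import GuideHit
from .locus import CodonMatrix, CodonRecord

logger = logging.getLogger(__name__)

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY*")

GC_FILTER_THRESHOLD = 75.0  # type-specific queries drop guides above this %


@dataclass(frozen=True)
class SignedDistance:
    """Signed nt distance from cut site to codon; positive means upstream."""

    value: int

    @property
    def upstream(self) -> bool:
        return self.value >= 0

    def __int__(self) -> int:
        return self.value


@dataclass(frozen=True)
class ResidueQuery:
    """Parameters of a position-specific or type-specific query.

    ``mode="position"`` targets the residue at a 1-based ``position``, keeping
    guides whose cut lies within ``max_distance`` nt (None = unlimited, i.e.
    all guides within the input locus).  ``mode="type"`` targets every residue
    of ``amino_acid`` (single-letter code; '*' addresses a terminal stop).
    """

    mode: str
    position: int | None = None
    max_distance: int | None = None
    amino_acid: str | None = None

    def __post_init__(self):
        if self.mode not in ("position", "type"):
            raise ValueError(f"unknown query mode {self.mode!r}")
        if self.mode == "position" and self.position is None:
            raise ValueError("position-specific query requires a residue position")
        if self.mode == "type":
            if self.amino_acid is None or self.amino_acid.upper() not in AMINO_ACIDS:
                raise ValueError(
                    f"type-specific query requires a single-letter amino acid, "
                    f"got {self.amino_acid!r}"
                )
            if self.amino_acid == "*":
                logger.info("type-specific query for the stop codon '*'")


def distance_to_codon(hit: GuideHit, residue: CodonRecord) -> SignedDistance:
    """Signed distance from a guide's cut site to a residue's codon."""
    c = hit.cut5_index
    left = residue.base_positions[0]
    right = residue.base_positions[2]
    if c + 1 <= left:  # cut entirely 5' of the codon: guide upstream
        value = left - (c + 1) if hit.strand == "forward" else left - c
    elif c >= right:  # cut entirely 3' of the codon: guide downstream
        value = right - c if hit.strand == "forward" else right - (c + 1)
    else:  # cut within the codon's genomic span
        value = 0
    return SignedDistance(value)


def _nearest_key(item: tuple[GuideHit, int]) -> tuple:
    hit, dist = item
    return (abs(dist), hit.strand != "forward", hit.protospacer)


def query_position(
    guides: list[GuideHit], matrix: CodonMatrix, q: ResidueQuery
) -> tuple[list[tuple[GuideHit, int]], list[tuple[GuideHit, int]]]:
    """Position-specific query: window, split and sort guides around a residue.

    Returns ``(upstream, downstream)`` lists of ``(hit, signed_distance)``.
    Guides beyond ``max_distance`` are removed; the upstream (positive,
    including 0) list is sorted by decreasing distance and the downstream
    (negative) list by increasing magnitude, so both read toward the codon.
    """
    if q.position is None or not 1 <= q.position <= len(matrix):
        raise PositionError(
            f"residue position {q.position} outside protein of length {len(matrix)}"
        )
    residue = matrix[q.position]
    upstream: list[tuple[GuideHit, int]] = []
    downstream: list[tuple[GuideHit, int]] = []
    for hit in guides:
        d = distance_to_codon(hit, residue).value
        if q.max_distance is not None and abs(d) > q.max_distance:
            continue
        (upstream if d >= 0 else downstream).append((hit, d))
    upstream.sort(key=lambda item: (-item[1], item[0].strand != "forward", item[0].protospacer))
    downstream.sort(key=lambda item: (-item[1], item[0].strand != "forward", item[0].protospacer))
    return upstream, downstream


@dataclass(frozen=True)
class ResiduePairRow:
    """The closest 5' and 3' guides for one residue of the queried type."""

    position: int  # 1-based
    context: str  # +/-2 neighbours with '*' marking the target, '-'-padded
    five_prime: tuple[GuideHit, int] | None
    three_prime: tuple[GuideHit, int] | None


def _residue_context(matrix: CodonMatrix, position: int) -> str:
    """The two residues either side of the target, target shown as '*'."""
    protein = matrix.protein
    i = position - 1
    before = protein[max(i - 2, 0) : i].rjust(2, "-")
    after = protein[i + 1 : i + 3].ljust(2, "-")
    return before + "*" + after


def query_type(
    guides: list[GuideHit], matrix: CodonMatrix, q: ResidueQuery
) -> list[ResiduePairRow]:
    """Type-specific query: the closest 5'/3' guide pair for every residue
    of the queried amino-acid type.

    Guides with > 75% G/C content are removed before selection.  For each
    residue the minimum-|distance| guide with non-negative distance (the 5'
    guide) and the minimum-|distance| guide with negative distance (the 3'
    guide) are picked; a missing side is reported as None.  Ties prefer the
    forward strand, then the lexicographically smaller protospacer.
    """
    aa = (q.amino_acid or "").upper() if q.amino_acid != "*" else "*"
    surviving = [h for h in guides if h.gc_percent <= GC_FILTER_THRESHOLD]
    rows: list[ResiduePairRow] = []
    targets = [r for r in matrix.residues if r.amino_acid == aa]
    if not targets:
        logger.info("amino acid %r not present in the protein; empty report", aa)
        return rows
    for residue in targets:
        five: list[tuple[GuideHit, int]] = []
        three: list[tuple[GuideHit, int]] = []
        for hit in surviving:
            d = distance_to_codon(hit, residue).value
            (five if d >= 0 else three).append((hit, d))
        rows.append(
            ResiduePairRow(
                position=residue.index,
                context=_residue_context(matrix, residue.index),
                five_prime=min(five, key=_nearest_key) if five else None,
                three_prime=min(three, key=_nearest_key) if three else None,
            )
        )
    return rows
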