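"""Candidate gRNA discovery on both strands, with per-guide annotations.

Guides are 20-nt protospacers adjacent to a PAM.  Supported PAMs:

* ``NGG`` — SpCas9: 3' PAM, blunt cut 3 nt 5' of the PAM.
* ``YG``  — relaxed 3' motif, same cut geometry as NGG.
* ``TTTN`` — Cas12a: 5' PAM, proximal cut of the staggered pair placed after
  protospacer base 18 (18 nt 3' of the PAM end).

Each hit records ``cut5_index``: the 0-based coordinate, on the FORWARD locus,
of the base immediately 5' of the physical cut.  The cut therefore lies
between forward indices ``cut5_index`` and ``cut5_index + 1`` for hits on
either strand, which makes downstream distance arithmetic strand-uniform.

PAM matching is performed on the uppercased sequence: nucleases act on
genomic DNA irrespective of gene structure, so guides may span intron/exon
boundaries and the flanks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

from .locus import AnnotatedLocus, reverse_complement

logger = logging.getLogger(__name__)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

PROTOSPACER_LENGTH = 20


@dataclass(frozen=True)
class PamSpec:
    """A supported PAM and its cut geometry.

    ``side`` is where the PAM sits relative to the protospacer on the
    protospacer strand.  ``cut_offset`` is the signed offset from the PAM
    start (protospacer-strand coordinates) to the base immediately 5' of the
    cut: -4 encodes the SpCas9 blunt cut 3 nt 5' of a 3' PAM; +21 encodes the
    Cas12a proximal cut after protospacer base 18 of a 4-nt 5' PAM
    (4 + 18 - 1).
    """

    name: str
    pattern: str
    side: str  # "3prime" or "5prime" of the protospacer
    protospacer_length: int = PROTOSPACER_LENGTH
    cut_offset: int = -4

    def protospacer_span(self, pam_start: int) -> tuple[int, int]:
        """Half-open protospacer span on the protospacer strand."""
        if self.side == "3prime":
            return pam_start - self.protospacer_length, pam_start
        start = pam_start + len(self.pattern)
        return start, start + self.protospacer_length

    def cut5(self, pam_start: int) -> int:
        """Base immediately 5' of the cut, protospacer-strand coordinates."""
        return pam_start + self.cut_offset


PAMS: Mapping[str, PamSpec] = {
    "NGG": PamSpec("NGG", "NGG", "3prime", cut_offset=-4),
    "YG": PamSpec("YG", "YG", "3prime", cut_offset=-4),
    "TTTN": PamSpec("TTTN", "TTTN", "5prime", cut_offset=21),
}


@dataclass(frozen=True)
class GuideHit:
    """One candidate gRNA in guide-strand orientation."""

    protospacer: str
    pam: str
    strand: str  # "forward" | "reverse" relative to the input locus sense
    cut5_index: int  # forward-locus coordinate of the base 5' of the cut
    gc_percent: float = 0.0
    leading_g: bool = False
    poly_t: bool = False
    high_gc: bool = False
    offtarget_count: int | None = None

    def sort_key(self) -> tuple:
        return (self.cut5_index, self.strand != "forward", self.protospacer)


def _matches_iupac(seq: str, pattern: str, at: int) -> bool:
    for i, p in enumerate(pattern):
        if seq[at + i] not in IUPAC[p]:
            return False
    return True


def find_pam_sites(seq: str, pam: PamSpec) -> list[int]:
    """All 0-based start coordinates where the PAM motif matches.

    Overlapping matches are all reported.  Matching is case-insensitive
    (the sequence is uppercased first).
    """
    seq = seq.upper()
    plen = len(pam.pattern)
    return [
        c for c in range(len(seq) - plen + 1) if _matches_iupac(seq, pam.pattern, c)
    ]


def gc_content(protospacer: str) -> float:
    """G/C percentage of a protospacer (0-100)."""
    s = protospacer.upper()
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


def annotate_notes(hit: GuideHit) -> GuideHit:
    """Populate the poly-T, leading-G and high-G/C annotations of a hit.

    Poly-T means a tandem run of four or more Ts anywhere in the protospacer
    (it terminates Pol III transcription of the guide); leading G is the
    protospacer starting with G (favoured by U6/T7 promoters); high G/C is
    > 75%.
    """
    return replace(
        hit,
        poly_t="TTTT" in hit.protospacer.upper(),
        leading_g=hit.protospacer.upper().startswith("G"),
        high_gc=hit.gc_percent > 75.0,
    )


def extract_guides(locus: AnnotatedLocus | str, pam: PamSpec) -> list[GuideHit]:
    """Find every candidate guide on both strands of the locus.

    The forward strand is scanned directly and the reverse strand via the
    reverse complement, with reverse-hit coordinates mapped back onto the
    forward locus.  Hits whose protospacer would extend beyond the available
    sequence (flanks included) are dropped.  Results are sorted by
    ``cut5_index``, forward strand before reverse at ties, then by
    protospacer.
    """
    seq = locus.sequence if isinstance(locus, AnnotatedLocus) else locus
    seq = seq.upper()
    total = len(seq)
    hits: list[GuideHit] = []
    for strand, s in (("forward", seq), ("reverse", reverse_complement(seq))):
        for pam_start in find_pam_sites(s, pam):
            a, b = pam.protospacer_span(pam_start)
            if a < 0 or b > total:
                continue
            c_local = pam.cut5(pam_start)
            cut5 = c_local if strand == "forward" else total - 2 - c_local
            hit = GuideHit(
                protospacer=s[a:b],
                pam=s[pam_start : pam_start + len(pam.pattern)],
                strand=strand,
                cut5_index=cut5,
                gc_percent=gc_content(s[a:b]),
            )
            hits.append(annotate_notes(hit))
    hits.sort(key=GuideHit.sort_key)
    return hits


def _count_overlapping(haystack: str, needle: str) -> int:
    n = 0
    i = haystack.find(needle)
    while i != -1:
        n += 1
        i = haystack.find(needle, i + 1)
    return n


def count_offtargets(protospacer: str, genome: Iterable[tuple[str, str]]) -> int:
    """Count additional exact genomic occurrences of a protospacer.

    Exact (mismatch-free) substring occurrences of the protospacer are counted
    in every genome record and in each record's reverse complement; matches
    never span record boundaries.  One match is subtracted for the on-target
    site itself, and the result is floored at 0 (the guide may lie in flanking
    sequence absent from the genome file).  A palindromic protospacer is
    counted once per strand occurrence.
    """
    protospacer = protospacer.upper()
    total = 0
    seen_any = False
    for _rec_id, seq in genome:
        seen_any = True
        seq = seq.upper()
        total += _count_overlapping(seq, protospacer)
        total += _count_overlapping(reverse_complement(seq), protospacer)
    if not seen_any:
        logger.warning("off-target counting against an empty genome; returning 0")
        return 0
    return max(total - 1, 0)
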