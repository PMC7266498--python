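"""End-to-end orchestration: locus -> guides -> query -> report."""

from __future__ import annotations

import logging
from dataclasses import replace

from .genome import Genome
from .guides import PAMS, PamSpec, count_offtargets, extract_guides
from .locus import build_codon_matrix, parse_locus, validate_cds
from .query import ResidueQuery, query_position, query_type
from .report import GuideReport, build_position_report, build_type_report

logger = logging.getLogger(__name__)


def _with_offtargets(guides, genome: Genome | None):
    if genome is None:
        logger.warning("no genome supplied; off-target counts left blank")
        return guides
    return [
        replace(h, offtarget_count=count_offtargets(h.protospacer, genome))
        for h in guides
    ]


def design_guides(
    raw_locus: str,
    cds: str,
    query: ResidueQuery,
    pam: PamSpec | str = "NGG",
    upstream_flank: str = "",
    downstream_flank: str = "",
    genome: Genome | None = None,
) -> GuideReport:
    """Run the full design pipeline and return a rendered report.

    The locus is parsed from its case encoding, the supplied CDS is checked
    against the exon-derived one, candidate guides are discovered on both
    strands for the chosen PAM, annotated and (when a genome is given)
    off-target counted, and finally filtered and ordered according to the
    query.
    """
    if isinstance(pam, str):
        pam = PAMS[pam.upper()]
    locus = parse_locus(raw_locus, upstream_flank, downstream_flank)
    validate_cds(locus, cds)
    matrix = build_codon_matrix(locus, cds)
    guides = _with_offtargets(extract_guides(locus, pam), genome)
    if query.mode == "position":
        upstream, downstream = query_position(guides, matrix, query)
        return build_position_report(upstream, downstream)
    return build_type_report(query_type(guides, matrix, query))
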