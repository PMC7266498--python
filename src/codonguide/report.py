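"""CSV report rendering for the two query modes.

Column sets and order are fixed.  Position-specific reports have one row per
guide; type-specific reports have one row per targeted residue with two
repeated per-guide column groups, the first for the closest 5' guide and the
second for the closest 3' guide.  G/C content is rendered with one decimal,
distances as plain signed integers, and the Notes field is a semicolon-joined
set of flags ("polyT"; "leading G"; "G/C > 75%").  An off-target count of
None (no genome supplied) renders as an empty cell.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass

from .errors import OutputError
from .guides import GuideHit
from .query import ResiduePairRow

POSITION_COLUMNS = [
    "gRNA Sequence",
    "PAM",
    "Strand",
    "G/C Content",
    "Distance from aa (bp)",
    "Notes",
    "Off-target Count",
]

_PER_GUIDE_TYPE_COLUMNS = [
    "PAM",
    "Strand",
    "G/C Content",
    "Distance of cut site from Amino Acid (bp)",
    "Notes",
    "Off-target Count",
]

TYPE_COLUMNS = [
    "Amino Acid Position",
    "Adjacent amino acids",
    "5' gRNA Sequence",
    "3' gRNA Sequence",
    *_PER_GUIDE_TYPE_COLUMNS,  # the 5' guide
    *_PER_GUIDE_TYPE_COLUMNS,  # the 3' guide
]


@dataclass(frozen=True)
class GuideReport:
    """An ordered, already-rendered CSV report."""

    mode: str  # "position" | "type"
    header: tuple[str, ...]
    rows: tuple[tuple[str, ...], ...]


def render_notes(hit: GuideHit) -> str:
    notes = []
    if hit.poly_t:
        notes.append("polyT")
    if hit.leading_g:
        notes.append("leading G")
    if hit.high_gc:
        notes.append("G/C > 75%")
    return "; ".join(notes)


def _guide_cells(item: tuple[GuideHit, int] | None) -> list[str]:
    if item is None:
        return [""] * len(_PER_GUIDE_TYPE_COLUMNS)
    hit, dist = item
    return [
        hit.pam,
        hit.strand,
        f"{hit.gc_percent:.1f}",
        str(dist),
        render_notes(hit),
        "" if hit.offtarget_count is None else str(hit.offtarget_count),
    ]


def build_position_report(
    upstream: list[tuple[GuideHit, int]], downstream: list[tuple[GuideHit, int]]
) -> GuideReport:
    """Render a position-specific query result: 5' guides first (decreasing
    distance), then 3' guides (increasing magnitude)."""
    rows = []
    for hit, dist in list(upstream) + list(downstream):
        rows.append(
            (
                hit.protospacer,
                hit.pam,
                hit.strand,
                f"{hit.gc_percent:.1f}",
                str(dist),
                render_notes(hit),
                "" if hit.offtarget_count is None else str(hit.offtarget_count),
            )
        )
    return GuideReport("position", tuple(POSITION_COLUMNS), tuple(rows))


def build_type_report(pairs: list[ResiduePairRow]) -> GuideReport:
    """Render a type-specific query result, one row per targeted residue."""
    rows = []
    for pair in pairs:
        row = [
            str(pair.position),
            pair.context,
            pair.five_prime[0].protospacer if pair.five_prime else "",
            pair.three_prime[0].protospacer if pair.three_prime else "",
        ]
        row += _guide_cells(pair.five_prime)
        row += _guide_cells(pair.three_prime)
        rows.append(tuple(row))
    return GuideReport("type", tuple(TYPE_COLUMNS), tuple(rows))


def write_report(report: GuideReport, path: str | os.PathLike) -> None:
    """Write the report as RFC-4180 CSV with the fixed header row."""
    try:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(report.header)
            writer.writerows(report.rows)
    except OSError as exc:
        raise OutputError(f"could not write report to {path!s}: {exc}") from exc
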