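"""Distance rules, position-specific windowing, type-specific pair selection."""

import pytest

from codonguide import (
    GuideHit,
    PositionError,
    ResidueQuery,
    build_codon_matrix,
    distance_to_codon,
    parse_locus,
    query_position,
    query_type,
)
from codonguide.locus import CodonRecord

from conftest import oracle_distance


def hit(cut5, strand="forward", proto="ACGTACGTACGTACGTACGT", gc=50.0, pam="AGG"):
    return GuideHit(
        protospacer=proto, pam=pam, strand=strand, cut5_index=cut5, gc_percent=gc
    )


CODON = CodonRecord(index=10, amino_acid="C", codon="TGT", base_positions=(27, 28, 29))


class TestDistanceToCodon:
    @pytest.mark.parametrize(
        "cut5, strand, expected",
        [
            (20, "forward", 6),    # upstream: right of cut (21) to codon left (27)
            (20, "reverse", 7),    # upstream: left of cut (20) to codon left (27)
            (35, "forward", -6),   # downstream: left of cut (35) to codon right (29)
            (35, "reverse", -7),   # downstream: right of cut (36) to codon right (29)
            (28, "forward", 0),    # cut inside the codon
            (28, "reverse", 0),
            (26, "forward", 0),    # cut immediately abuts the codon start
            (29, "forward", 0),    # cut immediately abuts the codon end
            (29, "reverse", -1),
            (26, "reverse", 1),
        ],
    )
    def test_four_printed_rules_and_zero_case(self, cut5, strand, expected):
        assert distance_to_codon(hit(cut5, strand), CODON).value == expected

    def test_agrees_with_independent_rule_oracle(self):
        for cut5 in range(0, 60):
            for strand in ("forward", "reverse"):
                got = distance_to_codon(hit(cut5, strand), CODON).value
                assert got == oracle_distance(strand, cut5, 27, 29)

    def test_intron_split_codon_measures_genomic_endpoints(self):
        split = CodonRecord(
            index=2, amino_acid="C", codon="TGT", base_positions=(3, 4, 9)
        )
        # cut between 6 and 7 sits in the intron inside the codon span
        assert distance_to_codon(hit(6, "forward"), split).value == 0
        # downstream distances count the intervening intron
        assert distance_to_codon(hit(15, "forward"), split).value == -6

    def test_zero_distance_classified_upstream(self):
        assert distance_to_codon(hit(28, "forward"), CODON).upstream


def guides_at(*specs):
    """GuideHits engineered to have given (distance, strand[, gc]) to CODON."""
    out = []
    for i, spec in enumerate(specs):
        d, strand = spec[0], spec[1]
        gc = spec[2] if len(spec) > 2 else 50.0
        left, right = CODON.base_positions[0], CODON.base_positions[2]
        if d > 0:
            cut5 = left - d - 1 if strand == "forward" else left - d
        elif d < 0:
            cut5 = right - d if strand == "forward" else right - d - 1
        else:
            cut5 = left
        proto = f"{'ACGT' * 5}"[: 20 - len(str(i))] + str(i)  # unique label
        out.append(hit(cut5, strand, proto=proto, gc=gc))
    return out


MATRIX = build_codon_matrix(
    parse_locus("a" * 27 + "TGTTGCTGT" + "a" * 24)
)  # residues 1-3 are cysteines at genomic [27..35]


class TestQueryPosition:
    def test_out_of_range_position(self):
        with pytest.raises(PositionError):
            query_position([], MATRIX, ResidueQuery("position", position=99))

    def test_window_split_and_sort(self):
        guides = guides_at((25, "forward"), (5, "forward"), (-10, "reverse"))
        q = ResidueQuery("position", position=1, max_distance=30)
        up, down = query_position(guides, MATRIX, q)
        assert [d for _h, d in up] == [25, 5]  # decreasing distance
        assert [d for _h, d in down] == [-10]  # increasing magnitude

    def test_boundary_distance_excluded(self):
        guides = guides_at((31, "forward"), (30, "forward"))
        up, down = query_position(
            guides, MATRIX, ResidueQuery("position", position=1, max_distance=30)
        )
        assert [d for _h, d in up] == [30]
        assert down == []

    def test_zero_window_with_no_in_codon_cut_is_empty(self):
        guides = guides_at((12, "forward"), (-4, "reverse"))
        up, down = query_position(
            guides, MATRIX, ResidueQuery("position", position=1, max_distance=0)
        )
        assert up == [] and down == []

    def test_unlimited_window_keeps_everything(self):
        guides = guides_at((250, "forward"), (-180, "reverse"))
        up, down = query_position(
            guides, MATRIX, ResidueQuery("position", position=1)
        )
        assert len(up) == 1 and len(down) == 1

    def test_enlarging_the_window_is_monotone(self):
        guides = guides_at(
            (3, "forward"), (9, "reverse"), (-7, "forward"), (21, "forward"), (-30, "reverse")
        )
        kept_before: set = set()
        for radius in (0, 5, 10, 25, 40):
            up, down = query_position(
                guides, MATRIX, ResidueQuery("position", position=1, max_distance=radius)
            )
            kept = {h.protospacer for h, _d in up + down}
            assert kept_before <= kept
            kept_before = kept

    def test_downstream_sort_reads_toward_increasing_magnitude(self):
        guides = guides_at((-12, "forward"), (-3, "reverse"), (-25, "forward"))
        _up, down = query_position(
            guides, MATRIX, ResidueQuery("position", position=1, max_distance=30)
        )
        assert [d for _h, d in down] == [-3, -12, -25]


class TestQueryType:
    def test_absent_amino_acid_yields_empty_report(self):
        rows = query_type([], MATRIX, ResidueQuery("type", amino_acid="W"))
        assert rows == []

    def test_nearest_pair_per_residue(self):
        guides = guides_at((40, "forward"), (8, "forward"), (-5, "reverse"), (-22, "forward"))
        rows = query_type(guides, MATRIX, ResidueQuery("type", amino_acid="C"))
        row1 = rows[0]  # residue 1 is the codon the distances were built for
        assert row1.five_prime[1] == 8
        assert row1.three_prime[1] == -5

    def test_high_gc_decoy_removed_before_selection(self):
        guides = guides_at((4, "forward", 80.0), (15, "forward", 50.0))
        rows = query_type(guides, MATRIX, ResidueQuery("type", amino_acid="C"))
        assert rows[0].five_prime[1] == 15  # the 80% G/C guide was filtered

    def test_missing_side_is_explicit(self):
        guides = guides_at((9, "forward"),)
        rows = query_type(guides, MATRIX, ResidueQuery("type", amino_acid="C"))
        assert rows[0].five_prime is not None
        assert rows[0].three_prime is None

    def test_context_marks_target_and_pads_termini(self):
        rows = query_type([], MATRIX, ResidueQuery("type", amino_acid="C"))
        # protein is CCC: '-' pads where fewer than two neighbours exist
        assert [r.context for r in rows] == ["--*CC", "-C*C-", "CC*--"]

    def test_every_residue_of_the_type_gets_a_row(self):
        rows = query_type([], MATRIX, ResidueQuery("type", amino_acid="C"))
        assert [r.position for r in rows] == [1, 2, 3]


class TestResidueQueryValidation:
    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            ResidueQuery("motif")

    def test_type_mode_requires_valid_amino_acid(self):
        with pytest.raises(ValueError):
            ResidueQuery("type", amino_acid="B")

    def test_stop_codon_queries_are_permitted(self):
        q = ResidueQuery("type", amino_acid="*")
        assert q.amino_acid == "*"
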